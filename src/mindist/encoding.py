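"""Triplet encoding of hairpin sequence/structure into a 256-dimensional vector.

Each nucleotide of a single stem-loop gets a pairing status: 0 for an
unpaired stem position (bulge / internal loop / external dangle), 1 for the
left-hand side of a base pair, 2 for the right-hand side, 3 for a position
inside the terminal loop (the unpaired block enclosed by the innermost base
pair). A length-3 window slides over the hairpin; every window is summarized
by its midpoint nucleotide together with the status of all three positions,
which addresses one of 4 (nucleotides) x 4^3 (status triples) = 256 counters.
Counts are normalized to a frequency vector.

Windows lie fully inside the sequence (no padding), so a hairpin of length L
contributes L - 2 windows. Under the default ``windows`` normalization the
vector therefore sums to exactly 1; the ``length`` variant divides by L
instead (sum (L-2)/L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import HairpinRecord, check_balanced

__all__ = [
    "NUCLEOTIDE_ORDER",
    "PairingStatusArray",
    "TripletVector",
    "TripletEncoder",
    "pairing_status",
    "triplet_index",
    "triplet_label",
    "encode",
    "encode_batch",
]

#: Nucleotide rank used for the index layout: the first vector position is
#: (A,0,0,0) and the last is (G,3,3,3). Pure convention — all downstream
#: distances are invariant under any fixed reindexing.
NUCLEOTIDE_ORDER = "ACUG"
_NT_RANK = {nt: i for i, nt in enumerate(NUCLEOTIDE_ORDER)}

_HAIRPIN_LOOP_RE = re.compile(r"\((\.*)\)")


class StructureError(ValueError):
    """Structure is not a single stem-loop usable by the encoder."""


@dataclass(frozen=True)
class PairingStatusArray:
    """Per-nucleotide pairing statuses of a single stem-loop."""

    statuses: np.ndarray  # int8, values in {0,1,2,3}

    def __post_init__(self) -> None:
        s = self.statuses
        if (s == 1).sum() != (s == 2).sum():
            raise StructureError("left/right pair-side counts differ")

    def __len__(self) -> int:
        return len(self.statuses)


@dataclass(frozen=True)
class TripletVector:
    """Normalized 256-position triplet count vector for one hairpin."""

    values: np.ndarray
    source_id: str
    raw_counts: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        if self.values.shape != (256,) or self.raw_counts.shape != (256,):
            raise ValueError("triplet vector must have exactly 256 components")


def pairing_status(structure: str) -> PairingStatusArray:
    """Assign pairing statuses to every position of a dot-bracket string.

    The structure must be balanced, contain at least one base pair and have
    exactly one hairpin loop (one maximal run of dots directly enclosed by a
    base pair). Multibranch or multi-hairpin structures are rejected.
    """
    if set(structure) - set("(.)"):
        raise StructureError("invalid dot-bracket characters")
    if not check_balanced(structure):
        raise StructureError("unbalanced structure")
    if "(" not in structure:
        raise StructureError("structure has zero base pairs")
    loops = list(_HAIRPIN_LOOP_RE.finditer(structure))
    if len(loops) != 1:
        raise StructureError(f"not a single stem-loop ({len(loops)} hairpin loops)")
    statuses = np.zeros(len(structure), dtype=np.int8)
    arr = np.frombuffer(structure.encode(), dtype=np.uint8)
    statuses[arr == ord("(")] = 1
    statuses[arr == ord(")")] = 2
    loop = loops[0]
    statuses[loop.start(1) : loop.end(1)] = 3  # dots inside the innermost pair
    return PairingStatusArray(statuses)


def triplet_index(
    midpoint_nucleotide: str, status_prev: int, status_cur: int, status_next: int
) -> int:
    """Map (midpoint nucleotide, status triple) to a vector position in [0, 255].

    Layout is nucleotide-major: rank(nt)*64 + prev*16 + cur*4 + next with
    nucleotide ranks A=0, C=1, U=2, G=3.
    """
    try:
        rank = _NT_RANK[midpoint_nucleotide]
    except KeyError:
        raise ValueError(f"invalid nucleotide {midpoint_nucleotide!r}") from None
    for s in (status_prev, status_cur, status_next):
        if s not in (0, 1, 2, 3):
            raise ValueError(f"invalid pairing status {s!r}")
    return rank * 64 + status_prev * 16 + status_cur * 4 + status_next


def triplet_label(index: int) -> str:
    """Human-readable label of a vector position, e.g. ``'A000'`` or ``'G333'``."""
    nt = NUCLEOTIDE_ORDER[index // 64]
    rest = index % 64
    return f"{nt}{rest // 16}{(rest % 16) // 4}{rest % 4}"


def encode(record: HairpinRecord, normalization: str = "windows") -> TripletVector:
    """Encode one hairpin into its normalized triplet vector.

    ``normalization='windows'`` (default) divides counts by the number of
    windows, L-2, so the components sum to 1; ``'length'`` divides by the
    sequence length L.
    """
    if normalization not in ("windows", "length"):
        raise ValueError(f"unknown normalization {normalization!r}")
    statuses = pairing_status(record.structure).statuses.astype(np.intp)
    seq = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    rank = np.full(256, -1, dtype=np.intp)
    for nt, r in _NT_RANK.items():
        rank[ord(nt)] = r
    mid_rank = rank[seq[1:-1]]
    idx = mid_rank * 64 + statuses[:-2] * 16 + statuses[1:-1] * 4 + statuses[2:]
    raw = np.bincount(idx, minlength=256).astype(np.int64)
    n_windows = len(record) - 2
    denom = n_windows if normalization == "windows" else len(record)
    return TripletVector(
        values=raw / denom, source_id=record.id, raw_counts=raw, n_windows=n_windows
    )


def encode_batch(
    records: list[HairpinRecord], normalization: str = "windows"
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Encode many hairpins; failures are collected, not fatal.

    Returns an (n x 256) DataFrame indexed by record id with columns labeled
    by (nucleotide, status triple), plus a list of (id, reason) diagnostics
    for records that could not be encoded.
    """
    if not records:
        raise ValueError("empty input")
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    rows, index, diagnostics = [], [], []
    for rec in records:
        try:
            rows.append(encode(rec, normalization=normalization).values)
            index.append(rec.id)
        except (StructureError, ValueError) as exc:
            diagnostics.append((rec.id, str(exc)))
    columns = [triplet_label(i) for i in range(256)]
    table = pd.DataFrame(np.asarray(rows).reshape(len(rows), 256), index=index, columns=columns)
    table.index.name = "id"
    return table, diagnostics


class TripletEncoder(TransformerMixin, BaseEstimator):
    """Transformer from hairpin records to the 256-dim triplet representation.

    Stateless (``fit`` only validates the normalization); ``transform`` takes
    a list of :class:`~mindist.io.HairpinRecord` and returns an (n, 256)
    array. Records that cannot be encoded raise, matching sklearn transformer
    semantics; use :func:`encode_batch` for the diagnostic-collecting variant.
    """

    def __init__(self, normalization: str = "windows"):
        self.normalization = normalization

    def fit(self, X, y=None):
        if self.normalization not in ("windows", "length"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.n_features_out_ = 256
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([encode(rec, normalization=self.normalization).values for rec in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray([triplet_label(i) for i in range(256)], dtype=object)
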