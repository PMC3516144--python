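"""Readers and writers for hairpins, genomic intervals, annotations and cluster tables.

External formats handled here:

* Vienna dot-bracket records — three-line FASTA-like blocks
  (``>id`` header, RNA sequence, dot-bracket structure).
* BED4/BED6 — genomic intervals, 0-based half-open.
* GFF3 — annotation features (1-based inclusive on disk, converted to
  0-based half-open on read; only seqid/type/start/end/strand are used).
* TSV cluster tables — output of an external structural clustering
  (member_id, cluster_id, optional k_level).

All coordinates are kept 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GenomeInterval",
    "HairpinRecord",
    "ClusterAssignment",
    "HairpinValidationError",
    "read_vienna",
    "parse_vienna",
    "write_vienna",
    "read_bed",
    "write_bed",
    "attach_intervals",
    "read_gff3",
    "write_gff3",
    "read_cluster_table",
    "read_id_list",
]

_VALID_NT = frozenset("ACGU")
_STRANDS = frozenset("+-.")


class HairpinValidationError(ValueError):
    """A hairpin record violates a structural or sequence invariant."""


def check_balanced(structure: str) -> bool:
    """True iff every '(' is matched and no prefix closes more than it opens."""
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
    return depth == 0


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomeInterval") -> float:
        """Edge-to-edge distance in bp; 0 when overlapping or book-ended,
        ``inf`` across chromosomes. Strand is ignored."""
        if self.chrom != other.chrom:
            return float("inf")
        if self.end <= other.start:
            return float(other.start - self.end)
        if other.end <= self.start:
            return float(self.start - other.end)
        return 0.0


@dataclass
class HairpinRecord:
    """One candidate or known precursor: sequence plus its MFE dot-bracket structure.

    On construction the sequence is uppercased and DNA T is mapped to U;
    sequence/structure length mismatch, unbalanced structures, sequences
    shorter than 3 nt (no triplet window would exist) and non-ACGU(T)
    characters are rejected.
    """

    id: str
    sequence: str
    structure: str
    interval: Optional[GenomeInterval] = None
    is_known: bool = False
    family: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if not self.id:
            raise HairpinValidationError("empty record id")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise HairpinValidationError(
                f"{self.id}: invalid sequence characters {sorted(bad)}"
            )
        if len(self.sequence) != len(self.structure):
            raise HairpinValidationError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        if len(self.sequence) < 3:
            raise HairpinValidationError(f"{self.id}: sequence shorter than 3 nt")
        if set(self.structure) - set("(.)"):
            raise HairpinValidationError(f"{self.id}: invalid structure characters")
        if not check_balanced(self.structure):
            raise HairpinValidationError(f"{self.id}: unbalanced structure")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClusterAssignment:
    """Membership of one hairpin in one structural cluster at one k-level."""

    member_id: str
    cluster_id: str
    k_level: Optional[float] = None


# ---------------------------------------------------------------------------
# Vienna dot-bracket records


def parse_vienna(text: str, strict: bool = False) -> list[HairpinRecord]:
    """Parse three-line Vienna records from a string.

    Invalid records are skipped with a warning unless ``strict`` is set.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise ValueError("Vienna input is not made of (header, sequence, structure) triples")
    records: list[HairpinRecord] = []
    for i in range(0, len(lines), 3):
        header, seq, struct = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header at record {i // 3 + 1}, got {header!r}")
        rec_id = header[1:].split()[0] if header[1:].split() else ""
        try:
            records.append(HairpinRecord(id=rec_id, sequence=seq, structure=struct))
        except HairpinValidationError as exc:
            if strict:
                raise
            warnings.warn(f"skipping record {rec_id!r}: {exc}", stacklevel=2)
    return records


def read_vienna(path: str | Path, strict: bool = False) -> list[HairpinRecord]:
    """Read hairpin records from a Vienna dot-bracket file."""
    return parse_vienna(Path(path).read_text(), strict=strict)


def write_vienna(records: Iterable[HairpinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structure}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> dict[str, GenomeInterval]:
    """Read BED4/BED6 into a mapping of name -> interval.

    Lines with start >= end are rejected with a warning; the optional
    column 6 supplies the strand.
    """
    intervals: dict[str, GenomeInterval] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns (name required)")
        chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
        strand = cols[5] if len(cols) >= 6 and cols[5] in _STRANDS else "."
        try:
            intervals[name] = GenomeInterval(chrom, start, end, strand)
        except ValueError as exc:
            warnings.warn(f"{path}:{lineno}: rejected BED line ({exc})", stacklevel=2)
    return intervals


def write_bed(records: Iterable[HairpinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            if iv is None:
                continue
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.id}\t0\t{iv.strand}\n")


def attach_intervals(
    records: Iterable[HairpinRecord], intervals: dict[str, GenomeInterval]
) -> list[str]:
    """Attach BED intervals to matching records; return unmatched BED names."""
    by_id = {rec.id: rec for rec in records}
    unmatched = []
    for name, iv in intervals.items():
        rec = by_id.get(name)
        if rec is None:
            unmatched.append(name)
        else:
            rec.interval = iv
    if unmatched:
        warnings.warn(f"{len(unmatched)} BED name(s) with no matching hairpin id", stacklevel=2)
    return unmatched


# ---------------------------------------------------------------------------
# GFF3 annotation


def read_gff3(path: str | Path) -> list[tuple[GenomeInterval, str]]:
    """Read a GFF3 annotation as (interval, feature_type) pairs.

    GFF3 is 1-based inclusive; intervals are converted to the internal
    0-based half-open convention.
    """
    features: list[tuple[GenomeInterval, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"{path}:{lineno}: GFF3 needs >= 8 columns")
        chrom, _source, ftype = cols[0], cols[1], cols[2]
        start, end = int(cols[3]) - 1, int(cols[4])
        strand = cols[6] if cols[6] in _STRANDS else "."
        features.append((GenomeInterval(chrom, start, end, strand), ftype))
    return features


def write_gff3(
    features: Iterable[tuple[GenomeInterval, str]], path: str | Path, source: str = "mindist"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype in features:
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# Cluster tables and id lists


def read_cluster_table(path: str | Path) -> list[ClusterAssignment]:
    """Read a TSV of structural cluster assignments.

    Columns: member_id, cluster_id, optional k_level. A header row is
    optional. A member assigned to two clusters at the same k-level is an
    error; assignments at distinct k-levels are distinct partitions.
    """
    first = Path(path).read_text().splitlines()[0] if Path(path).read_text() else ""
    has_header = "member_id" in first
    if has_header:
        df = pd.read_csv(path, sep="\t", dtype={"member_id": str, "cluster_id": str})
    else:
        ncols = len(first.split("\t"))
        names = ["member_id", "cluster_id", "k_level"][: max(ncols, 2)]
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str)
    if "k_level" not in df.columns:
        df["k_level"] = None
    dup = df.duplicated(subset=["member_id", "k_level"], keep=False)
    if dup.any():
        dupes = sorted(df.loc[dup, "member_id"].unique())
        raise ValueError(f"duplicate member(s) within one k_level: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        k = None if pd.isna(row.k_level) or row.k_level is None else float(row.k_level)
        out.append(ClusterAssignment(str(row.member_id), str(row.cluster_id), k))
    return out


def read_id_list(path: str | Path) -> list[str]:
    """Read ids, one per line (first whitespace-separated token)."""
    ids = []
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if tok:
            ids.append(tok[0])
    return ids
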