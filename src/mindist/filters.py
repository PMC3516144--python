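"""Annotation-compatibility and genomic-proximity filtering of accepted candidates.

Candidates overlapping features annotated as exons, transposons or other
non-coding RNAs are unlikely to host a pre-miRNA and are removed; intronic or
unannotated loci are kept. Survivors can be further restricted to putative
miRNA genomic cluster members: loci within 50 kb of a known precursor, and
enumerations of genomically proximal subsets inside structural clusters.

Genomic distance is the edge-to-edge gap between intervals (0 when they
overlap), computed on the same chromosome only, ignoring strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ClusterAssignment, GenomeInterval, HairpinRecord

__all__ = [
    "DEFAULT_INCOMPATIBLE_TYPES",
    "DEFAULT_TYPE_MAP",
    "AnnotationIndex",
    "GenomicCluster",
    "GenomicClusterSet",
    "annotation_filter",
    "proximity_filter",
    "enumerate_genomic_clusters",
    "cluster_report",
]

#: Feature types whose overlap disqualifies a candidate. Matching is
#: case-insensitive after applying DEFAULT_TYPE_MAP to the GFF3 type column.
DEFAULT_INCOMPATIBLE_TYPES = frozenset({"exon", "transposon", "ncrna"})

#: Dialect normalization for GFF3 column 3 (extend per annotation source).
DEFAULT_TYPE_MAP = {
    "transposable_element": "transposon",
    "transposable element": "transposon",
    "te": "transposon",
    "noncoding_rna": "ncrna",
    "ncrna": "ncrna",
    "snorna": "ncrna",
    "snrna": "ncrna",
    "trna": "ncrna",
    "rrna": "ncrna",
}


class AnnotationIndex:
    """Interval index over annotation features with a configurable
    incompatible-type vocabulary."""

    def __init__(
        self,
        features: Iterable[tuple[GenomeInterval, str]],
        incompatible_types: frozenset[str] = DEFAULT_INCOMPATIBLE_TYPES,
        type_map: Optional[Mapping[str, str]] = None,
    ):
        self.incompatible_types = frozenset(t.lower() for t in incompatible_types)
        self.type_map = dict(DEFAULT_TYPE_MAP if type_map is None else type_map)
        self._trees: dict[str, IntervalTree] = {}
        for iv, ftype in features:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, self._normalize(ftype)
            )

    def _normalize(self, ftype: str) -> str:
        t = ftype.lower()
        return self.type_map.get(t, t)

    def overlapping_types(self, interval: GenomeInterval) -> set[str]:
        """Feature types of all annotations overlapping the query by >= 1 bp."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(interval.start, interval.end)}

    def is_compatible(self, interval: GenomeInterval) -> bool:
        """True when no overlapping annotation has an incompatible type
        (introns and unannotated regions are compatible)."""
        return not (self.overlapping_types(interval) & self.incompatible_types)


def annotation_filter(
    candidates: Sequence[HairpinRecord],
    annotation: AnnotationIndex,
    missing_interval: str = "keep",
) -> tuple[list[str], dict[str, str]]:
    """Remove candidates overlapping incompatible annotation.

    Returns (retained ids, per-candidate verdict). Candidates without a
    genomic interval are excluded from filtering: kept with a warning by
    default (``missing_interval='keep'``), or dropped/raised per the flag.
    """
    if missing_interval not in ("keep", "drop", "error"):
        raise ValueError("missing_interval must be keep|drop|error")
    retained, verdicts = [], {}
    for rec in candidates:
        if rec.interval is None:
            if missing_interval == "error":
                raise ValueError(f"candidate {rec.id} has no genomic interval")
            verdicts[rec.id] = "no-interval"
            if missing_interval == "keep":
                warnings.warn(f"candidate {rec.id} has no interval; kept unfiltered",
                              stacklevel=2)
                retained.append(rec.id)
            continue
        bad = annotation.overlapping_types(rec.interval) & annotation.incompatible_types
        if bad:
            verdicts[rec.id] = "removed:" + ",".join(sorted(bad))
        else:
            verdicts[rec.id] = "retained"
            retained.append(rec.id)
    return retained, verdicts


def proximity_filter(
    candidates: Sequence[HairpinRecord],
    known_intervals: Sequence[GenomeInterval],
    max_gap: int = 50_000,
) -> list[str]:
    """Retain candidates within ``max_gap`` bp (inclusive) of a known precursor.

    Distance is the same-chromosome edge gap; overlapping or contained loci
    count as distance 0. Candidates without an interval are removed.
    """
    retained = []
    for rec in candidates:
        if rec.interval is None:
            continue
        gap = min((rec.interval.gap_to(iv) for iv in known_intervals), default=float("inf"))
        if gap <= max_gap:
            retained.append(rec.id)
    return retained


@dataclass(frozen=True)
class GenomicCluster:
    """A set of genomically proximal loci inside one structural cluster."""

    member_ids: frozenset[str]
    structural_cluster_id: str
    composition: str  # all-known | mixed | all-candidate
    median_pairwise_distance: float
    chrom: str
    span_start: int
    span_end: int
    anchor_id: Optional[str] = None


@dataclass(frozen=True)
class GenomicClusterSet:
    clusters: list[GenomicCluster]
    max_gap: int
    mode: str

    def __len__(self) -> int:
        return len(self.clusters)


def _median_pairwise_gap(intervals: Sequence[GenomeInterval]) -> float:
    gaps = [
        a.gap_to(b)
        for a, b in combinations(intervals, 2)
        if a.chrom == b.chrom
    ]
    return float(np.median(gaps)) if gaps else float("nan")


def _composition(members: Sequence[HairpinRecord]) -> str:
    known = [m.is_known for m in members]
    if all(known):
        return "all-known"
    if any(known):
        return "mixed"
    return "all-candidate"


def _make_cluster(
    members: Sequence[HairpinRecord], cluster_id: str, anchor_id: Optional[str] = None
) -> GenomicCluster:
    ivs = [m.interval for m in members]
    return GenomicCluster(
        member_ids=frozenset(m.id for m in members),
        structural_cluster_id=cluster_id,
        composition=_composition(members),
        median_pairwise_distance=_median_pairwise_gap(ivs),
        chrom=ivs[0].chrom,
        span_start=min(iv.start for iv in ivs),
        span_end=max(iv.end for iv in ivs),
        anchor_id=anchor_id,
    )


def _connected_components(members: Sequence[HairpinRecord], max_gap: int) -> list[list[HairpinRecord]]:
    """Single-linkage chaining on the gap <= max_gap adjacency graph."""
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if members[i].interval.gap_to(members[j].interval) <= max_gap:
            parent[find(i)] = find(j)
    comps: dict[int, list[HairpinRecord]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(members[i])
    return list(comps.values())


def _anchored_clusters(
    members: Sequence[HairpinRecord], cluster_id: str, max_gap: int, chaining: bool
) -> list[GenomicCluster]:
    out = []
    seen: set[frozenset[str]] = set()
    for anchor in (m for m in members if m.is_known):
        if chaining:
            comp = next(
                c
                for c in _connected_components(members, max_gap)
                if any(m.id == anchor.id for m in c)
            )
            group = comp
        else:
            group = [
                m
                for m in members
                if m.id == anchor.id or m.interval.gap_to(anchor.interval) <= max_gap
            ]
        key = frozenset(m.id for m in group)
        if len(group) >= 2 and key not in seen:
            seen.add(key)
            out.append(_make_cluster(group, cluster_id, anchor_id=anchor.id))
    return out


def enumerate_genomic_clusters(
    members: Sequence[HairpinRecord],
    structural_clusters,
    mode: str = "precursor_anchored",
    max_gap: int = 50_000,
    anchored_chaining: bool = False,
) -> GenomicClusterSet:
    """Enumerate putative miRNA genomic clusters inside structural clusters.

    ``mode='precursor_anchored'``: for each known precursor in a structural
    cluster, collect cluster members within ``max_gap`` of it (direct
    distance-to-anchor by default; ``anchored_chaining`` grows the set by
    single linkage instead). ``mode='candidate_only'``: single-linkage
    chaining among all members at gap <= ``max_gap``, no anchor required;
    resulting sets that are subsets of the anchored output are discarded.
    Members lacking an interval, and empty structural clusters, are skipped
    with a warning.
    """
    if mode not in ("precursor_anchored", "candidate_only"):
        raise ValueError("mode must be precursor_anchored|candidate_only")
    if isinstance(structural_clusters, Mapping):
        amap = {str(k): str(v) for k, v in structural_clusters.items()}
    else:
        amap = {a.member_id: a.cluster_id for a in structural_clusters}
    by_id = {m.id: m for m in members}
    groups: dict[str, list[HairpinRecord]] = {}
    for mid, cid in amap.items():
        rec = by_id.get(mid)
        if rec is None or rec.interval is None:
            warnings.warn(f"member {mid} missing record or interval; skipped", stacklevel=2)
            continue
        groups.setdefault(cid, []).append(rec)
    clusters: list[GenomicCluster] = []
    for cid in sorted(groups):
        recs = groups[cid]
        if not recs:
            warnings.warn(f"structural cluster {cid} is empty; skipped", stacklevel=2)
            continue
        anchored = _anchored_clusters(recs, cid, max_gap, anchored_chaining)
        if mode == "precursor_anchored":
            clusters.extend(anchored)
        else:
            anchored_sets = [c.member_ids for c in anchored]
            for comp in _connected_components(recs, max_gap):
                if len(comp) < 2:
                    continue
                key = frozenset(m.id for m in comp)
                if any(key <= s for s in anchored_sets):
                    continue  # already covered by the anchored enumeration
                clusters.append(_make_cluster(comp, cid))
    return GenomicClusterSet(clusters=clusters, max_gap=max_gap, mode=mode)


def cluster_report(cluster_set: GenomicClusterSet) -> pd.DataFrame:
    """Tabular summary: members, composition, median pairwise distance, span."""
    rows = [
        {
            "structural_cluster": c.structural_cluster_id,
            "anchor": c.anchor_id,
            "n_members": len(c.member_ids),
            "members": ",".join(sorted(c.member_ids)),
            "composition": c.composition,
            "median_pairwise_distance": c.median_pairwise_distance,
            "chrom": c.chrom,
            "span_start": c.span_start,
            "span_end": c.span_end,
        }
        for c in cluster_set.clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "structural_cluster",
            "anchor",
            "n_members",
            "members",
            "composition",
            "median_pairwise_distance",
            "chrom",
            "span_start",
            "span_end",
        ],
    )
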