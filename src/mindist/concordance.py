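"""Agreement between feature-space geometry and an external structural clustering.

Two questions are answered here. First, do members of externally derived
structural clusters sit closer to their own cluster centroid than to any
other centroid in the PCA feature space (proportion of correct assignments,
tested against an identity-shuffled null with Welch's t)? Second, are the
known precursors compact — is the median distance of knowns to their own
centroid smaller than for random identity subsets of the same size?

The randomization keeps every point where it is and only permutes which
identity sits at which position, so the spatial density of the cloud is held
fixed under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClusterAssignment

__all__ = [
    "ConcordanceResult",
    "CompactnessResult",
    "centroid",
    "proportion_correct",
    "shuffle_identities",
    "concordance_test",
    "compactness_test",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Welch-test comparison of observed vs identity-shuffled correct-assignment rates."""

    proportion_correct: float
    p_value: float
    t_statistic: float
    df: float
    average_cluster_size: float
    n_samples: int
    observed: np.ndarray = field(repr=False, default=None)
    shuffled: np.ndarray = field(repr=False, default=None)
    k_level: Optional[float] = None


@dataclass(frozen=True)
class CompactnessResult:
    """Median distance of the knowns to their centroid against a randomized null."""

    median_distance: float
    p_value: float
    p_value_normal: float
    null_medians: np.ndarray = field(repr=False, default=None)

    @property
    def n_null(self) -> int:
        return len(self.null_medians)


def _coords_frame(coords) -> pd.DataFrame:
    if not isinstance(coords, pd.DataFrame):
        raise TypeError("coords must be a DataFrame indexed by member id")
    return coords


def _assignment_map(assignments) -> dict[str, str]:
    if isinstance(assignments, Mapping):
        return {str(k): str(v) for k, v in assignments.items()}
    out: dict[str, str] = {}
    for a in assignments:
        if not isinstance(a, ClusterAssignment):
            raise TypeError("assignments must be ClusterAssignment or a mapping")
        if a.member_id in out:
            raise ValueError(f"duplicate assignment for {a.member_id}")
        out[a.member_id] = a.cluster_id
    return out


def centroid(coords) -> np.ndarray:
    """Per-dimension arithmetic mean of a set of coordinates."""
    arr = coords.to_numpy(dtype=float) if isinstance(coords, pd.DataFrame) else np.asarray(
        coords, dtype=float
    )
    if arr.size == 0:
        raise ValueError("centroid of an empty set")
    return arr.mean(axis=0)


def proportion_correct(coords: pd.DataFrame, assignments) -> float:
    """Fraction of members at least as close to their own cluster centroid
    as to any other cluster's centroid.

    Ties count as correct, so singleton clusters (whose member coincides with
    its own centroid) are always correct. Members without coordinates raise.
    """
    coords = _coords_frame(coords)
    amap = _assignment_map(assignments)
    if not amap:
        raise ValueError("no assignments given")
    missing = [m for m in amap if m not in coords.index]
    if missing:
        raise KeyError(f"members without coordinates: {missing[:5]}")
    clusters = sorted({c for c in amap.values()})
    cindex = {c: i for i, c in enumerate(clusters)}
    members = list(amap)
    X = coords.loc[members].to_numpy(dtype=float)
    C = np.vstack(
        [coords.loc[[m for m in members if amap[m] == c]].to_numpy(dtype=float).mean(axis=0)
         for c in clusters]
    )
    D = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2)
    own = np.array([cindex[amap[m]] for m in members])
    d_own = D[np.arange(len(members)), own]
    if len(clusters) == 1:
        return 1.0
    D_other = D.copy()
    D_other[np.arange(len(members)), own] = np.inf
    return float((d_own <= D_other.min(axis=1)).mean())


def shuffle_identities(coords: pd.DataFrame, seed) -> pd.DataFrame:
    """Permute the id-to-coordinate mapping, keeping every position occupied.

    A Fisher–Yates sequence of transpositions yields a uniformly random
    permutation of identities over the fixed coordinate multiset.
    ``seed`` may be an int or a numpy Generator (reused across calls).
    """
    coords = _coords_frame(coords)
    if len(coords) < 2:
        raise ValueError("need at least 2 members to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(coords))
    shuffled = pd.DataFrame(
        coords.to_numpy()[perm], index=coords.index, columns=coords.columns
    )
    # the swap scheme conserves the coordinate multiset by construction
    assert np.array_equal(
        np.sort(shuffled.to_numpy(), axis=0), np.sort(coords.to_numpy(), axis=0)
    )
    return shuffled


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        # exact-tie convention for degenerate zero-variance groups
        if a.mean() == b.mean():
            return 0.0, 1.0, float(len(a) + len(b) - 2)
        return float("inf"), 0.0, float(len(a) + len(b) - 2)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def concordance_test(
    samples: Sequence[tuple[pd.DataFrame, object]],
    seed=None,
    k_level: Optional[float] = None,
) -> ConcordanceResult:
    """Welch two-sample t test of observed vs shuffled correct-assignment proportions.

    For every (coords, assignments) sample the observed proportion correct and
    the proportion on one identity-shuffled replicate are computed; the two
    groups of proportions are compared with Welch's unequal-variance,
    two-sided t test.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    observed, shuffled, sizes = [], [], []
    for coords, assignments in samples:
        amap = _assignment_map(assignments)
        observed.append(proportion_correct(coords, amap))
        shuffled.append(proportion_correct(shuffle_identities(coords, rng), amap))
        sizes.append(len(amap) / len(set(amap.values())))
    obs, shuf = np.asarray(observed), np.asarray(shuffled)
    t, p, df = _welch(obs, shuf)
    return ConcordanceResult(
        proportion_correct=float(obs.mean()),
        p_value=p,
        t_statistic=t,
        df=df,
        average_cluster_size=float(np.mean(sizes)),
        n_samples=len(samples),
        observed=obs,
        shuffled=shuf,
        k_level=k_level,
    )


def _median_distance_to_centroid(X: np.ndarray) -> float:
    c = X.mean(axis=0)
    return float(np.median(np.linalg.norm(X - c, axis=1)))


def compactness_test(
    coords: pd.DataFrame,
    known_ids: Iterable[str],
    n_null: int = 1000,
    seed=None,
) -> CompactnessResult:
    """Test whether known precursors are unusually compact in feature space.

    Observed statistic: median Euclidean distance of the knowns to their own
    centroid. Null: the same statistic on ``n_null`` equal-size random
    identity subsets of the full coordinate set (positions fixed, identities
    randomized). Reports the empirical one-sided p-value
    (1 + #{null <= observed}) / (1 + n_null), which is bounded below by
    1/(1+n_null), and alongside it a normal approximation from the null mean
    and standard deviation for comparison with vanishingly small tail
    probabilities.
    """
    coords = _coords_frame(coords)
    known_ids = list(dict.fromkeys(known_ids))
    if len(known_ids) < 2:
        raise ValueError("need at least 2 known precursors")
    if n_null < 100:
        raise ValueError("need n_null >= 100 for a meaningful empirical p-value")
    missing = [k for k in known_ids if k not in coords.index]
    if missing:
        raise KeyError(f"known ids without coordinates: {missing[:5]}")
    X = coords.to_numpy(dtype=float)
    observed = _median_distance_to_centroid(coords.loc[known_ids].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    k, n = len(known_ids), len(coords)
    null = np.array(
        [
            _median_distance_to_centroid(X[rng.choice(n, size=k, replace=False)])
            for _ in range(n_null)
        ]
    )
    p_emp = (1 + int((null <= observed).sum())) / (1 + n_null)
    sd = null.std(ddof=1)
    if sd == 0.0:
        p_norm = 1.0 if observed >= null.mean() else 0.0
    else:
        p_norm = float(stats.norm.cdf((observed - null.mean()) / sd))
    return CompactnessResult(
        median_distance=observed, p_value=p_emp, p_value_normal=p_norm, null_medians=null
    )
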