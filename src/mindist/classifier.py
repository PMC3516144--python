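"""The MinDist classifier: minimum distance to known precursors with a
resampling-calibrated cutoff.

A candidate's score is its Euclidean distance in feature space to the nearest
known precursor (smaller = more precursor-like); it is accepted when the
score is at most a maximum-distance cutoff. The cutoff is calibrated by
repeatedly splitting the known pool: a fraction (one representative per
miRNA family) serves as reference, the remaining knowns are positive test
examples, and equal-size candidate samples are negative examples. On each
split the ROC over all observed cutoffs yields the Youden-optimal cutoff
c* = argmax_c {TPR(c) - FPR(c)}; average optimal cutoffs at several training
fractions follow a log-linear trend in the fraction, which is extrapolated to
fraction 1.0 to obtain the operating cutoff for the full reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "SampleEvaluation",
    "AverageROC",
    "CutoffModel",
    "SelectionResult",
    "Sample",
    "MinDistClassifier",
    "min_distance",
    "roc_and_youden",
    "make_samples",
    "evaluate_samples",
    "fit_cutoff_model",
    "select_candidates",
    "calibrate_cutoff",
]


@dataclass(frozen=True)
class SampleEvaluation:
    """ROC of one train/test split over the full cutoff grid."""

    cutoffs: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    youden_j: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    f1: float
    train_fraction: float = float("nan")


@dataclass(frozen=True)
class AverageROC:
    """Average performance over many splits across the full cutoff range.

    ``operating_tpr``/``operating_fpr`` are the means of the per-sample rates
    at each sample's own optimal cutoff, which can differ from the optimum of
    the averaged curve.
    """

    cutoffs: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)
    mean_fpr: np.ndarray = field(repr=False)
    mean_youden_j: float
    mean_optimal_cutoff: float
    operating_tpr: float
    operating_fpr: float


@dataclass(frozen=True)
class CutoffModel:
    """Log-linear fit of average optimal cutoff vs training fraction."""

    fractions: np.ndarray
    avg_cutoffs: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    extrapolated_cutoff: float
    form: str = "log-cutoff"


@dataclass(frozen=True)
class SelectionResult:
    """Candidates inside the acceptance region at a given maximum distance."""

    accepted_ids: list[str]
    scores: dict[str, float] = field(repr=False)
    cutoff_used: float

    @property
    def acceptance_fraction(self) -> float:
        return len(self.accepted_ids) / len(self.scores) if self.scores else 0.0


@dataclass(frozen=True)
class Sample:
    """One resampled train/test split of knowns and candidates."""

    train_pos: tuple[str, ...]
    test_pos: tuple[str, ...]
    train_neg: tuple[str, ...]
    test_neg: tuple[str, ...]


def min_distance(candidate_coords, reference_coords) -> np.ndarray:
    """Euclidean distance of each candidate to its nearest reference."""
    C = np.atleast_2d(np.asarray(candidate_coords, dtype=float))
    R = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    if R.shape[0] == 0:
        raise ValueError("empty reference set")
    return cdist(C, R).min(axis=1)


def roc_and_youden(
    pos_scores, neg_scores, train_fraction: float = float("nan")
) -> SampleEvaluation:
    """ROC over all observed cutoffs for distance-like scores (lower = positive).

    A prediction is positive iff score <= c. The cutoff grid is the set of
    distinct observed scores; TPR and FPR are non-decreasing in c. Among
    cutoffs tying on the Youden index the smallest is returned, minimizing
    false positives.
    """
    pos = np.sort(np.asarray(pos_scores, dtype=float))
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need non-empty positive and negative score lists")
    cutoffs = np.unique(np.concatenate([pos, neg]))
    tpr = np.searchsorted(pos, cutoffs, side="right") / pos.size
    fpr = np.searchsorted(neg, cutoffs, side="right") / neg.size
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    c_star = float(cutoffs[best])
    sens, spec = float(tpr[best]), float(1.0 - fpr[best])
    tp, fp = tpr[best] * pos.size, fpr[best] * neg.size
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = 2 * precision * sens / (precision + sens) if precision + sens > 0 else 0.0
    return SampleEvaluation(
        cutoffs=cutoffs,
        tpr=tpr,
        fpr=fpr,
        youden_j=float(j[best]),
        optimal_cutoff=c_star,
        sensitivity=sens,
        specificity=spec,
        f1=float(f1),
        train_fraction=train_fraction,
    )


def make_samples(
    known_ids: Sequence[str],
    candidate_ids: Sequence[str],
    train_fraction: float,
    n_samples: int,
    seed=None,
    families: Optional[Mapping[str, str]] = None,
) -> list[Sample]:
    """Draw resampled train/test splits of the known pool and candidates.

    Each sample takes ``train_fraction`` of the known pool as positive
    training examples with at most one representative per miRNA family, the
    remaining knowns as positive test examples, and disjoint random candidate
    subsets of matching sizes as negatives. When ``families`` is None every
    known is its own family.
    """
    known_ids = list(known_ids)
    candidate_ids = list(candidate_ids)
    if not known_ids:
        raise ValueError("empty known pool")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = max(1, round(train_fraction * len(known_ids)))
    if n_train >= len(known_ids):
        raise ValueError("train_fraction leaves no positive test examples")
    fam = {k: (families[k] if families else k) for k in known_ids}
    by_family: dict[str, list[str]] = {}
    for k in known_ids:
        by_family.setdefault(fam[k], []).append(k)
    if len(by_family) < n_train:
        raise ValueError(
            f"cannot draw {n_train} single-family representatives from "
            f"{len(by_family)} families"
        )
    n_test = len(known_ids) - n_train
    if len(candidate_ids) < n_train + n_test:
        raise ValueError("candidate pool too small for disjoint negative sets")
    rng = np.random.default_rng(seed)
    family_names = sorted(by_family)
    samples = []
    for _ in range(n_samples):
        chosen = rng.choice(len(family_names), size=n_train, replace=False)
        train_pos = tuple(
            by_family[family_names[i]][rng.integers(len(by_family[family_names[i]]))]
            for i in chosen
        )
        test_pos = tuple(k for k in known_ids if k not in set(train_pos))
        perm = rng.permutation(len(candidate_ids))
        train_neg = tuple(candidate_ids[i] for i in perm[:n_train])
        test_neg = tuple(candidate_ids[i] for i in perm[n_train : n_train + n_test])
        samples.append(Sample(train_pos, test_pos, train_neg, test_neg))
    return samples


def _step_interp(grid: np.ndarray, cutoffs: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Right-continuous step interpolation of a per-cutoff rate onto a grid."""
    idx = np.searchsorted(cutoffs, grid, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, len(values) - 1)], 0.0)
    return out


def evaluate_samples(
    samples: Sequence[Sample],
    coords: pd.DataFrame,
    train_fraction: float = float("nan"),
) -> tuple[list[SampleEvaluation], AverageROC]:
    """Score every split and average the ROC curves on a common cutoff grid.

    Per sample, test positives and negatives are scored by minimum distance to
    the sample's positive training references and run through
    :func:`roc_and_youden`. The average curve step-interpolates every sample
    onto the union grid of observed cutoffs; the average operating point is
    the mean (FPR, TPR) at each sample's own optimal cutoff.
    """
    if not samples:
        raise ValueError("no samples")
    evals = []
    for s in samples:
        ref = coords.loc[list(s.train_pos)].to_numpy(dtype=float)
        pos = min_distance(coords.loc[list(s.test_pos)].to_numpy(dtype=float), ref)
        neg = min_distance(coords.loc[list(s.test_neg)].to_numpy(dtype=float), ref)
        evals.append(roc_and_youden(pos, neg, train_fraction=train_fraction))
    grid = np.unique(np.concatenate([e.cutoffs for e in evals]))
    mean_tpr = np.mean([_step_interp(grid, e.cutoffs, e.tpr) for e in evals], axis=0)
    mean_fpr = np.mean([_step_interp(grid, e.cutoffs, e.fpr) for e in evals], axis=0)
    avg = AverageROC(
        cutoffs=grid,
        mean_tpr=mean_tpr,
        mean_fpr=mean_fpr,
        mean_youden_j=float(np.mean([e.youden_j for e in evals])),
        mean_optimal_cutoff=float(np.mean([e.optimal_cutoff for e in evals])),
        operating_tpr=float(np.mean([e.sensitivity for e in evals])),
        operating_fpr=float(np.mean([1.0 - e.specificity for e in evals])),
    )
    return evals, avg


def fit_cutoff_model(
    fractions: Sequence[float],
    avg_cutoffs: Sequence[float],
    form: str = "log-cutoff",
) -> CutoffModel:
    """Fit the log-linear cutoff model and extrapolate to the full pool.

    ``form='log-cutoff'`` (default) regresses ln(average cutoff) on the
    training fraction and evaluates at fraction 1.0; ``'log-fraction'``
    regresses the cutoff on ln(fraction) instead (extrapolation at ln 1 = 0).
    """
    f = np.asarray(fractions, dtype=float)
    c = np.asarray(avg_cutoffs, dtype=float)
    if len(np.unique(f)) < 3:
        raise ValueError("need at least 3 distinct training fractions")
    if np.any(c <= 0):
        raise ValueError("average cutoffs must be positive")
    if form == "log-cutoff":
        x, y = f, np.log(c)
    elif form == "log-fraction":
        x, y = np.log(f), c
    else:
        raise ValueError(f"unknown model form {form!r}")
    res = stats.linregress(x, y)
    if form == "log-cutoff":
        extrapolated = float(np.exp(res.intercept + res.slope * 1.0))
    else:
        extrapolated = float(res.intercept)
    return CutoffModel(
        fractions=f,
        avg_cutoffs=c,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        extrapolated_cutoff=extrapolated,
        form=form,
    )


def select_candidates(scores: Mapping[str, float], cutoff: float) -> SelectionResult:
    """Accept candidates whose minimum distance is at most the cutoff (inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    accepted = [cid for cid, s in scores.items() if s <= cutoff]
    return SelectionResult(accepted_ids=accepted, scores=dict(scores), cutoff_used=float(cutoff))


def calibrate_cutoff(
    coords: pd.DataFrame,
    known_ids: Sequence[str],
    candidate_ids: Sequence[str],
    fractions: Sequence[float] = (0.05, 0.10, 0.20, 0.50),
    n_samples: int = 1000,
    seed=None,
    families: Optional[Mapping[str, str]] = None,
    form: str = "log-cutoff",
) -> tuple[CutoffModel, dict[float, AverageROC]]:
    """Full calibration: resample at each fraction, average, fit, extrapolate."""
    rng = np.random.default_rng(seed)
    avg_by_fraction: dict[float, AverageROC] = {}
    avg_cutoffs = []
    for frac in fractions:
        samples = make_samples(
            known_ids,
            candidate_ids,
            train_fraction=frac,
            n_samples=n_samples,
            seed=int(rng.integers(2**31)),
            families=families,
        )
        _, avg = evaluate_samples(samples, coords, train_fraction=frac)
        avg_by_fraction[frac] = avg
        avg_cutoffs.append(avg.mean_optimal_cutoff)
    model = fit_cutoff_model(list(fractions), avg_cutoffs, form=form)
    return model, avg_by_fraction


class MinDistClassifier(BaseEstimator):
    """Nearest-known-precursor distance classifier in feature space.

    Parameters
    ----------
    cutoff : float, optional
        Maximum distance to the closest reference for acceptance (inclusive).
        If None, ``predict`` requires a cutoff fitted via
        :func:`calibrate_cutoff` and assigned to ``cutoff``; scoring methods
        work without one.

    The estimator follows sklearn conventions: ``fit(X)`` stores the
    reference coordinates (or ``fit(X, y)`` with boolean ``y`` selects the
    known rows), ``score_samples`` returns minimum distances, and
    ``decision_function`` returns ``cutoff - distance`` (positive = accepted)
    or ``-distance`` when no cutoff is set.
    """

    def __init__(self, cutoff: Optional[float] = None):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y is not None:
            mask = np.asarray(y).astype(bool)
            X = X[mask]
        if X.shape[0] == 0:
            raise ValueError("no reference precursors to fit on")
        self.reference_coords_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Minimum Euclidean distance of each row to the fitted references."""
        if not hasattr(self, "reference_coords_"):
            raise ValueError("classifier is not fitted")
        return min_distance(np.asarray(X, dtype=float), self.reference_coords_)

    def decision_function(self, X) -> np.ndarray:
        d = self.score_samples(X)
        return (self.cutoff - d) if self.cutoff is not None else -d

    def predict(self, X) -> np.ndarray:
        if self.cutoff is None:
            raise ValueError("no cutoff set; calibrate one or pass cutoff=")
        return self.score_samples(X) <= self.cutoff
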