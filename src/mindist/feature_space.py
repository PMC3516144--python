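"""Principal-components feature space over triplet vectors.

Many of the 256 triplet dimensions are structurally impossible (e.g. a
left-pair side immediately followed by a right-pair side) and therefore zero
for every hairpin; those zero-variance dimensions are dropped exactly. The
remaining dimensions are centered and scaled to unit variance, then rotated
to principal components. With all non-degenerate components retained the
mapping is an isometry of the scaled space, so minimum-distance results do
not depend on the rotation at all — the PCA buys independent coordinates,
not truncation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TripletFeatureSpace",
    "fit_feature_space",
    "project",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = "mindist-feature-space/1"


def _as_matrix(X) -> tuple[np.ndarray, object]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of vectors")
    return arr, None


class TripletFeatureSpace(TransformerMixin, BaseEstimator):
    """Zero-variance elimination + unit-variance scaling + PCA rotation.

    Parameters
    ----------
    n_components : int, optional
        Number of principal components to keep. By default every component
        with eigenvalue above ``eigenvalue_tol`` is retained, which makes the
        transform distance-preserving on the scaled space.
    eigenvalue_tol : float
        Components with explained variance at or below this are dropped as
        numerically degenerate.

    Attributes
    ----------
    kept_dims_ : ndarray of int
        Indices of input dimensions with nonzero variance in the fitting set
        (exact comparison on the raw values).
    means_, scales_ : ndarray
        Per-kept-dimension mean and standard deviation (ddof=1).
    loadings_ : ndarray, shape (n_components_, n_kept)
        Orthonormal principal axes, rows sorted by non-increasing eigenvalue.
        Sign convention: the largest-magnitude entry of each axis is positive.
    eigenvalues_ : ndarray
        Explained variances, non-increasing.
    """

    def __init__(self, n_components: int | None = None, eigenvalue_tol: float = 1e-12):
        self.n_components = n_components
        self.eigenvalue_tol = eigenvalue_tol

    def fit(self, X, y=None):
        M, _ = _as_matrix(X)
        n, p = M.shape
        if n < 2:
            raise ValueError("need at least 2 vectors to fit a feature space")
        kept = np.flatnonzero(M.max(axis=0) - M.min(axis=0) > 0)
        if kept.size == 0:
            raise ValueError("all dimensions have zero variance")
        Mk = M[:, kept]
        means = Mk.mean(axis=0)
        scales = Mk.std(axis=0, ddof=1)
        Ms = (Mk - means) / scales
        _, s, Vt = np.linalg.svd(Ms, full_matrices=False)
        eig = s**2 / (n - 1)
        if self.n_components is None:
            k = int((eig > self.eigenvalue_tol).sum())
        else:
            k = min(int(self.n_components), len(eig))
        if k < 1:
            raise ValueError("no component above the eigenvalue tolerance")
        Vt = Vt[:k].copy()
        # deterministic sign: largest-magnitude loading entry positive
        flip = Vt[np.arange(k), np.abs(Vt).argmax(axis=1)] < 0
        Vt[flip] *= -1.0
        self.n_features_in_ = p
        self.kept_dims_ = kept
        self.means_ = means
        self.scales_ = scales
        self.loadings_ = Vt
        self.eigenvalues_ = eig[:k]
        self.n_components_ = k
        return self

    def transform(self, X):
        """Project vectors to principal-component coordinates.

        DataFrame input yields a DataFrame indexed like the input with
        columns PC1..PCk; array input yields an (n, k) array.
        """
        if not hasattr(self, "loadings_"):
            raise ValueError("feature space is not fitted")
        M, index = _as_matrix(X)
        if M.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: got {M.shape[1]} features, expected {self.n_features_in_}"
            )
        coords = ((M[:, self.kept_dims_] - self.means_) / self.scales_) @ self.loadings_.T
        if index is not None:
            out = pd.DataFrame(
                coords, index=index, columns=[f"PC{i + 1}" for i in range(self.n_components_)]
            )
            out.index.name = "id"
            return out
        return coords


def fit_feature_space(vectors, n_components: int | None = None) -> TripletFeatureSpace:
    """Fit a feature space on a table of triplet vectors."""
    return TripletFeatureSpace(n_components=n_components).fit(vectors)


def project(model: TripletFeatureSpace, vectors):
    """Project triplet vectors with a fitted feature-space model."""
    return model.transform(vectors)


def save_model(model: TripletFeatureSpace, path: str | Path) -> None:
    """Serialize a fitted model losslessly to JSON."""
    doc = {
        "format": _FORMAT_VERSION,
        "n_features_in": int(model.n_features_in_),
        "n_components": int(model.n_components_),
        "kept_dims": model.kept_dims_.tolist(),
        "means": model.means_.tolist(),
        "scales": model.scales_.tolist(),
        "loadings": model.loadings_.tolist(),
        "eigenvalues": model.eigenvalues_.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TripletFeatureSpace:
    """Load a model saved by :func:`save_model`; rejects foreign or degenerate files."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt feature-space file: {exc}") from exc
    if doc.get("format") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format')!r}")
    if int(doc["n_components"]) < 1:
        raise ValueError("model with zero components")
    model = TripletFeatureSpace()
    model.n_features_in_ = int(doc["n_features_in"])
    model.n_components_ = int(doc["n_components"])
    model.kept_dims_ = np.asarray(doc["kept_dims"], dtype=int)
    model.means_ = np.asarray(doc["means"], dtype=float)
    model.scales_ = np.asarray(doc["scales"], dtype=float)
    model.loadings_ = np.asarray(doc["loadings"], dtype=float)
    model.eigenvalues_ = np.asarray(doc["eigenvalues"], dtype=float)
    if model.loadings_.shape != (model.n_components_, len(model.kept_dims_)):
        raise ValueError("inconsistent loadings shape")
    return model
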