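"""Feature preprocessing: [0,1] min-max scaling and PCA feature extraction.

Both transformers follow the scikit-learn fit/transform contract so they can
be fit on training folds only and applied unchanged to held-out folds. Their
fitted state serializes to plain JSON (per-column min/max, mean vector,
eigenvectors, eigenvalues) so a preprocessing pipeline can be shipped with a
trained model bundle.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MinMaxNormalizer",
    "PCATransform",
    "minmax_normalize",
    "pca_fit",
    "pca_transform",
    "save_preprocessing",
    "load_preprocessing",
]


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Per-column rescaling x -> (x - min) / (max - min).

    The column minimum maps to 0 and the maximum to 1. A constant column
    (max == min) maps to all zeros with a warning rather than dividing by
    zero, keeping the transform total on degenerate inputs. Held-out data
    transformed with a fitted normalizer may fall outside [0, 1]; no
    clipping is applied.

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (m,)
        Per-column extrema recorded at fit time.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        self._scaler = MinMaxScaler(clip=False).fit(X)
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        constant = np.isclose(self.data_max_, self.data_min_)
        if constant.any():
            cols = np.flatnonzero(constant).tolist()
            warnings.warn(
                f"constant column(s) {cols} mapped to 0 by min-max "
                "normalization",
                UserWarning,
                stacklevel=2,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, ensure_all_finite=True)
        return self._scaler.transform(X)

    def to_dict(self) -> dict:
        check_is_fitted(self, "data_min_")
        return {
            "kind": "minmax",
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        obj = cls()
        lo = np.asarray(d["data_min"], dtype=float)
        hi = np.asarray(d["data_max"], dtype=float)
        obj.fit(np.vstack([lo, hi]))
        return obj


class PCATransform(TransformerMixin, BaseEstimator):
    """PCA feature extraction via eigen-decomposition of the scatter matrix.

    Fits Z = (1/n) sum_i x_i x_i^T on mean-centered rows (the standard PCA
    covariance; set ``center=False`` for the raw second-moment variant) and
    projects rows onto the leading k eigenvectors.

    Parameters
    ----------
    retain : int or float, default 0.95
        If an int, the number k of components to keep (must be <= m).
        If a float in (0, 1], the smallest k whose cumulative eigenvalue
        fraction reaches that value.
    center : bool, default True
        Subtract the training mean before computing the scatter matrix and
        before projecting.

    Attributes
    ----------
    mean_ : ndarray of shape (m,)
        Training column means (zeros when ``center=False``).
    components_ : ndarray of shape (k, m)
        Orthonormal eigenvector rows, eigenvalue-descending. Sign fixed so
        each row's largest-magnitude entry is positive.
    eigenvalues_ : ndarray of shape (k,)
        Nonnegative, nonincreasing.
    k_ : int
        Retained dimension.
    """

    def __init__(self, retain=0.95, center: bool = True):
        self.retain = retain
        self.center = center

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        n, m = X.shape
        if n < 2:
            raise ValueError("PCA requires at least 2 instances")
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(m)
        Xc = X - self.mean_
        scatter = (Xc.T @ Xc) / n
        evals, evecs = np.linalg.eigh(scatter)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-magnitude component of each vector positive
        flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(m)])
        flip[flip == 0] = 1.0
        evecs = evecs * flip

        if isinstance(self.retain, (int, np.integer)) and not isinstance(
            self.retain, bool
        ):
            k = int(self.retain)
            if not 1 <= k <= m:
                raise ValueError(f"retain k={k} outside [1, {m}]")
        else:
            frac = float(self.retain)
            if not 0 < frac <= 1:
                raise ValueError("variance fraction must be in (0, 1]")
            total = evals.sum()
            if total <= 0:
                k = 1
            else:
                cum = np.cumsum(evals) / total
                k = int(np.searchsorted(cum, frac - 1e-12) + 1)
        self.k_ = k
        self.eigenvalues_ = evals[:k]
        self.components_ = evecs[:, :k].T
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, ensure_all_finite=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return (X - self.mean_) @ self.components_.T

    def to_dict(self) -> dict:
        check_is_fitted(self, "components_")
        return {
            "kind": "pca",
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "k": self.k_,
            "center": self.center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCATransform":
        obj = cls(retain=d["k"], center=d.get("center", True))
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.components_ = np.asarray(d["components"], dtype=float)
        obj.eigenvalues_ = np.asarray(d["eigenvalues"], dtype=float)
        obj.k_ = int(d["k"])
        obj.n_features_in_ = obj.components_.shape[1]
        return obj


def minmax_normalize(features):
    """Fit-and-apply min-max scaling; returns (normalized, fitted normalizer).

    The fitted normalizer records per-column min/max so the identical
    transform can be applied to held-out data.
    """
    norm = MinMaxNormalizer().fit(features)
    return norm.transform(features), norm


def pca_fit(features, retain=0.95, center: bool = True) -> PCATransform:
    """Fit a :class:`PCATransform` (see class docstring for conventions)."""
    return PCATransform(retain=retain, center=center).fit(features)


def pca_transform(model: PCATransform, features) -> np.ndarray:
    """Project rows onto the fitted model's retained components."""
    return model.transform(features)


def save_preprocessing(path, *transforms) -> None:
    """Serialize fitted transformers to one JSON document."""
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in transforms], fh)


def load_preprocessing(path) -> list:
    """Inverse of :func:`save_preprocessing`."""
    kinds = {"minmax": MinMaxNormalizer, "pca": PCATransform}
    with open(path) as fh:
        docs = json.load(fh)
    return [kinds[d["kind"]].from_dict(d) for d in docs]
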