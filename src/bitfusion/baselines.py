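"""Classical fixed combination rules used as benchmarks for the combiner.

All rules operate on one support slice at a time: a (p, l) matrix whose
column j is base classifier j's support vector over the p classes. The
published comparison names these rules without printing their formulas, so
each implementation follows the standard literature definition stated in its
docstring — a reconstruction of the named baseline, not a replication of any
particular implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .base_ensemble import SupportTensor

__all__ = [
    "MassFunction",
    "majority_vote",
    "distribution_summation",
    "dempster_shafer_fuse",
    "rank_fusion",
    "weighted_fusion",
    "entropy_weights",
    "BaselineCombiner",
    "BASELINE_METHODS",
]

BASELINE_METHODS = (
    "majority",
    "dist_sum",
    "dempster",
    "borda",
    "highest_rank",
    "entropy_w",
    "accuracy_w",
)


def _slice(xi_instance) -> np.ndarray:
    s = np.asarray(xi_instance, dtype=float)
    if s.ndim != 2 or s.shape[1] < 1:
        raise ValueError("expected a (p, l) support slice")
    return s


def majority_vote(xi_instance) -> int:
    """Plurality over the classifiers' argmax votes; ties to lowest index."""
    s = _slice(xi_instance)
    votes = np.bincount(s.argmax(axis=0), minlength=s.shape[0])
    return int(votes.argmax())


def distribution_summation(xi_instance) -> int:
    """Argmax of the per-class sum of soft supports (the mean rule up to
    scale); ties to lowest index."""
    s = _slice(xi_instance)
    return int(s.sum(axis=1).argmax())


@dataclass
class MassFunction:
    """Belief mass over the class frame Theta, with singleton and Theta
    focal elements only.

    ``singletons[i]`` is the mass on class i; ``theta`` the mass on the full
    frame (the uncommitted mass). Masses are nonnegative and sum to 1.
    """

    singletons: np.ndarray
    theta: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.singletons = np.asarray(self.singletons, dtype=float)
        total = self.singletons.sum() + self.theta
        if self.singletons.min() < 0 or self.theta < 0:
            raise ValueError("masses must be nonnegative")
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"masses must sum to 1 (got {total})")

    @classmethod
    def vacuous(cls, p: int) -> "MassFunction":
        return cls(np.zeros(p), 1.0)

    def combine(self, other: "MassFunction") -> "MassFunction":
        """Dempster's rule: normalized conjunctive combination.

        With singleton + Theta focal elements, the combined singleton mass
        is m1(i)m2(i) + m1(i)m2(T) + m1(T)m2(i) and the combined Theta mass
        m1(T)m2(T), renormalized by one minus the pairwise conflict.
        """
        a, b = self.singletons, other.singletons
        sing = a * b + a * other.theta + self.theta * b
        theta = self.theta * other.theta
        norm = sing.sum() + theta
        if norm <= 0:
            raise ValueError(
                "total conflict: Dempster combination has zero normalization"
            )
        return MassFunction(sing / norm, theta / norm)


def dempster_shafer_fuse(xi_instance, uncertainty: float = 0.1) -> int:
    """Combine per-classifier mass functions by Dempster's rule.

    Classifier j contributes mass (1-uncertainty) * xi[i, j] to each
    singleton {i} and the remaining ``uncertainty`` to the whole frame; the
    l masses are conjunctively combined and the maximal combined singleton
    wins (ties to lowest index). Requires soft (column-normalized) supports.
    """
    if not 0 <= uncertainty < 1:
        raise ValueError("uncertainty must lie in [0, 1)")
    s = _slice(xi_instance)
    p, l = s.shape
    combined = MassFunction.vacuous(p)
    for j in range(l):
        col = s[:, j]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"classifier {j} has an all-zero support column")
        mj = MassFunction((1 - uncertainty) * col / total, uncertainty)
        combined = combined.combine(mj)
    return int(combined.singletons.argmax())


def _rank_columns(s: np.ndarray) -> np.ndarray:
    """Per-classifier class ranks (0 = best), stable lowest-index ties."""
    p, l = s.shape
    ranks = np.empty((p, l), dtype=int)
    for j in range(l):
        order = np.argsort(-s[:, j], kind="stable")
        ranks[order, j] = np.arange(p)
    return ranks


def rank_fusion(xi_instance, scheme: str = "borda") -> int:
    """Rank-based combination.

    ``borda`` minimizes the summed rank over classifiers; ``highest_rank``
    minimizes the best (minimum) rank any classifier gave the class, then
    the second-best rank, and so on. All ties resolve to the lowest class
    index.
    """
    s = _slice(xi_instance)
    ranks = _rank_columns(s)
    if scheme == "borda":
        return int(ranks.sum(axis=1).argmin())
    if scheme == "highest_rank":
        keys = [tuple(sorted(ranks[i])) for i in range(s.shape[0])]
        return min(range(s.shape[0]), key=lambda i: (keys[i], i))
    raise ValueError(f"unknown rank scheme {scheme!r}")


def entropy_weights(xi_instance) -> np.ndarray:
    """Per-classifier confidence weights w_j = 1 - H(column j) / log p.

    A one-hot column (entropy 0) gets weight 1; a uniform column weight 0.
    """
    s = _slice(xi_instance)
    p = s.shape[0]
    if p < 2:
        raise ValueError("entropy weighting needs p >= 2 classes")
    cols = s / s.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cols > 0, cols * np.log(cols), 0.0)
    H = -terms.sum(axis=0)
    return 1.0 - H / np.log(p)


def weighted_fusion(xi_instance, weights=None, scheme: str = "accuracy") -> int:
    """Argmax of the weighted per-class support sum.

    ``scheme="entropy"`` derives per-instance weights from the columns'
    entropies; ``scheme="accuracy"`` (or any explicit use) requires
    nonnegative, not-all-zero ``weights`` — typically each classifier's
    held-out accuracy.
    """
    s = _slice(xi_instance)
    if scheme == "entropy":
        weights = entropy_weights(s)
    elif weights is None:
        raise ValueError(f"scheme {scheme!r} requires explicit weights")
    w = np.asarray(weights, dtype=float)
    if w.shape != (s.shape[1],):
        raise ValueError("need one weight per classifier")
    if w.min() < 0:
        raise ValueError("weights must be nonnegative")
    if not w.any():
        raise ValueError("weights must not be all zero")
    return int((s * w).sum(axis=1).argmax())


class BaselineCombiner(ClassifierMixin, BaseEstimator):
    """Fixed combination rule wrapped in the estimator interface.

    ``method`` is one of :data:`BASELINE_METHODS`. Only ``accuracy_w``
    learns anything at fit time: each classifier's accuracy on the provided
    (ideally out-of-fold) support tensor, used as its fusion weight.
    """

    def __init__(self, method: str = "majority",
                 ds_uncertainty: float = 0.1):
        self.method = method
        self.ds_uncertainty = ds_uncertainty

    def fit(self, X, y=None):
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"unknown fusion method {self.method!r}")
        if isinstance(X, SupportTensor):
            values, class_set = X.values, X.class_set
        else:
            values = np.asarray(X, dtype=float)
            class_set = tuple(range(values.shape[1]))
        self.classes_ = np.asarray(class_set)
        self.accuracy_weights_ = None
        if self.method == "accuracy_w":
            if y is None:
                raise ValueError("accuracy_w requires labels at fit time")
            lookup = {c: i for i, c in enumerate(class_set)}
            yi = np.array([lookup[v] for v in np.asarray(y)], dtype=int)
            arg = values.argmax(axis=1)  # (n, l)
            self.accuracy_weights_ = (arg == yi[:, None]).mean(axis=0)
            if not self.accuracy_weights_.any():
                # no classifier ever correct: degrade to uniform weights
                self.accuracy_weights_ = np.ones(values.shape[2])
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        values = X.values if isinstance(X, SupportTensor) else np.asarray(
            X, dtype=float
        )
        out = np.empty(values.shape[0], dtype=int)
        for i, s in enumerate(values):
            if self.method == "majority":
                out[i] = majority_vote(s)
            elif self.method == "dist_sum":
                out[i] = distribution_summation(s)
            elif self.method == "dempster":
                out[i] = dempster_shafer_fuse(s, self.ds_uncertainty)
            elif self.method == "borda":
                out[i] = rank_fusion(s, "borda")
            elif self.method == "highest_rank":
                out[i] = rank_fusion(s, "highest_rank")
            elif self.method == "entropy_w":
                out[i] = weighted_fusion(s, scheme="entropy")
            else:  # accuracy_w
                out[i] = weighted_fusion(s, self.accuracy_weights_)
        return self.classes_[out]
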