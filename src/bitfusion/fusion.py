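"""The bit-fusion combiner: weighted supports, threshold bits, online updates.

The combiner holds one real weight per (class, classifier) pair. For an
instance with support slice xi (p x l) it forms the elementwise activation
F = xi * wt, thresholds it at delta into a bit matrix B = [F > delta], and
predicts the class with the most bits in its row. Training is perceptron
style: per instance the bit matrix is compared with the one-hot target
pattern Omega (the true-class row replicated across classifier columns) and
the weights move multiplicatively,

    wt <- wt * (1 + eta * mu * E / n),

where E is the +/-1/0 error matrix, eta the learning coefficient, mu the
accelerator, and n the number of training instances (a damping term). The
per-epoch mean of the squared error entries is recorded as the MSE trace.

Two error-sign conventions ship. ``error_sign="output_minus_target"`` takes
E = B - Omega: from an all-zero bit matrix this *shrinks* true-class
weights, so no bit can
ever fire and prediction falls through to the fallback chain. The
``"target_minus_output"`` convention (E = Omega - B) grows a true-class
weight until its activation crosses delta and then stops — a self-calibrating
per-(class, classifier) threshold. Because the update is multiplicative a
weight can never change sign, so only the latter convention combined with
positive initial weights yields a combiner whose bit counts track the base
classifiers' votes; :meth:`FusionConfig.trainable` bundles that regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .base_ensemble import SupportTensor

__all__ = [
    "FusionConfig",
    "BitFusionCombiner",
    "FusionModel",
    "init_weights",
    "forward",
    "binarize",
    "instance_error",
    "update_weights",
    "train",
    "predict_fused",
    "FALLBACK_STAGES",
]

logger = logging.getLogger(__name__)

#: Ordered decision stages reported in prediction diagnostics.
FALLBACK_STAGES = (
    "bit_count",
    "weighted_support_sum",
    "base_majority_vote",
    "lowest_class_index",
)

# eta/mu pairs reported for the bit-fusion combiner on the six medical
# benchmarks (usable as named presets via FusionConfig.for_dataset)
REPORTED_COEFFICIENTS = {
    "leukemia": (0.5, 0.2),
    "breast_cancer": (0.2, 0.1),
    "lung_cancer": (0.3, 0.5),
    "hepatitis": (0.4, 0.4),
    "lymphoma": (0.2, 0.3),
    "embryonal_tumors": (0.6, 0.2),
}


@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the bit-fusion combiner.

    Defaults are the literal published regime: delta=0.9, eta=0.71,
    mu=1e-5, 100 epochs, symmetric [-0.5, 0.5] weight init, and the
    E = B - Omega error sign. In that regime eta*mu is so small that no
    activation ever crosses delta (see module docstring);
    :meth:`trainable` returns the regime in which the combiner actually
    learns.
    """

    delta: float = 0.9
    eta: float = 0.71
    mu: float = 0.00001
    epochs: int = 100
    seed: int = 0
    error_sign: str = "output_minus_target"
    weight_init: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.eta <= 0 or self.mu <= 0:
            raise ValueError("eta and mu must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.error_sign not in ("output_minus_target", "target_minus_output"):
            raise ValueError(f"unknown error_sign {self.error_sign!r}")
        if self.weight_init not in ("symmetric", "positive"):
            raise ValueError(f"unknown weight_init {self.weight_init!r}")

    @classmethod
    def trainable(cls, seed: int = 0, eta: float = 0.5, mu: float = 0.2,
                  **kw) -> "FusionConfig":
        """The learning regime: reported-magnitude coefficients,
        target-minus-output error sign, positive-half weight init."""
        return cls(
            eta=eta, mu=mu, seed=seed,
            error_sign="target_minus_output", weight_init="positive", **kw,
        )

    @classmethod
    def for_dataset(cls, name: str, seed: int = 0) -> "FusionConfig":
        """Trainable preset with the eta/mu pair reported for ``name``."""
        eta, mu = REPORTED_COEFFICIENTS[name]
        return cls.trainable(seed=seed, eta=eta, mu=mu)

    def replace(self, **kw) -> "FusionConfig":
        return replace(self, **kw)


def init_weights(p: int, l: int, seed: int,
                 weight_init: str = "symmetric") -> np.ndarray:
    """Initial p x l weight matrix, i.i.d. uniform.

    ``symmetric`` draws from [-0.5, 0.5); ``positive`` draws from [0, 0.5)
    (the positive half of the same interval — required for the multiplicative
    update to ever recruit a weight, since the update preserves sign).
    """
    if p < 2 or l < 1:
        raise ValueError("need p >= 2 classes and l >= 1 classifiers")
    rng = np.random.default_rng(seed)
    lo = -0.5 if weight_init == "symmetric" else 0.0
    return rng.uniform(lo, 0.5, size=(p, l))


def forward(xi_instance: np.ndarray, wt: np.ndarray) -> np.ndarray:
    """Elementwise activation F[i, j] = xi[i, j] * wt[i, j]."""
    xi_instance = np.asarray(xi_instance, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if xi_instance.shape != wt.shape:
        raise ValueError(
            f"shape mismatch: xi {xi_instance.shape} vs wt {wt.shape}"
        )
    return xi_instance * wt


def binarize(F: np.ndarray, delta: float) -> np.ndarray:
    """Bit matrix: 1 where the activation strictly exceeds delta, else 0."""
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    return (np.asarray(F, dtype=float) > delta).astype(np.int8)


def _omega(true_index: int, p: int, l: int) -> np.ndarray:
    om = np.zeros((p, l))
    om[true_index] = 1.0
    return om


def instance_error(B: np.ndarray, true_class, class_set,
                   error_sign: str = "output_minus_target") -> np.ndarray:
    """Per-instance error matrix, entries in {-1, 0, 1}.

    The target pattern Omega is the one-hot true-class row broadcast over
    all classifier columns. ``output_minus_target``: E = B - Omega;
    ``target_minus_output``: E = Omega - B.
    """
    class_set = tuple(class_set)
    if true_class not in class_set:
        raise ValueError(f"unknown class {true_class!r}")
    B = np.asarray(B, dtype=float)
    om = _omega(class_set.index(true_class), *B.shape)
    return B - om if error_sign == "output_minus_target" else om - B


def update_weights(wt: np.ndarray, E: np.ndarray, eta: float, mu: float,
                   n: int) -> np.ndarray:
    """One multiplicative step: wt' = wt + (eta * wt * mu * E) / n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    wt = np.asarray(wt, dtype=float)
    return wt + (eta * wt * mu * np.asarray(E, dtype=float)) / n


class BitFusionCombiner(ClassifierMixin, BaseEstimator):
    """Trainable bit-pattern combiner over a base-classifier support tensor.

    Parameters mirror :class:`FusionConfig`. ``fit`` expects the support
    tensor X — a :class:`~bitfusion.base_ensemble.SupportTensor` or a raw
    array of shape (n, p, l) — and per-instance labels y (members of the
    tensor's class_set, or integer class indices for a raw array).

    Attributes
    ----------
    classes_ : ndarray of the p class identifiers (tensor class order).
    weights_ : ndarray (p, l), trained weight matrix.
    mse_trace_ : ndarray (epochs,), per-epoch mean squared error entry.
    classifier_ids_ : tuple of l classifier identifiers.
    """

    def __init__(self, delta: float = 0.9, eta: float = 0.71,
                 mu: float = 0.00001, epochs: int = 100, seed: int = 0,
                 error_sign: str = "output_minus_target", weight_init: str = "symmetric"):
        self.delta = delta
        self.eta = eta
        self.mu = mu
        self.epochs = epochs
        self.seed = seed
        self.error_sign = error_sign
        self.weight_init = weight_init

    @classmethod
    def from_config(cls, config: FusionConfig) -> "BitFusionCombiner":
        return cls(**config.__dict__)

    @property
    def config(self) -> FusionConfig:
        return FusionConfig(
            delta=self.delta, eta=self.eta, mu=self.mu, epochs=self.epochs,
            seed=self.seed, error_sign=self.error_sign,
            weight_init=self.weight_init,
        )

    # -- helpers -----------------------------------------------------------

    def _coerce(self, X, y=None):
        """Return (values (n,p,l), classifier_ids, class_set, y_indices)."""
        if isinstance(X, SupportTensor):
            values = X.values
            class_set = X.class_set
            ids = X.classifier_ids
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 3:
                raise ValueError("support tensor must have shape (n, p, l)")
            class_set = tuple(range(values.shape[1]))
            ids = tuple(f"clf#{j}" for j in range(values.shape[2]))
        yi = None
        if y is not None:
            lookup = {c: i for i, c in enumerate(class_set)}
            try:
                yi = np.array([lookup[v] for v in np.asarray(y)], dtype=int)
            except KeyError as exc:
                raise ValueError(
                    f"label {exc.args[0]!r} not in the tensor's class set"
                ) from exc
        return values, ids, class_set, yi

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        self.config  # validates hyperparameters
        values, ids, class_set, yi = self._coerce(X, y)
        n, p, l = values.shape
        if n == 0:
            raise ValueError("empty support tensor")
        if len(yi) != n:
            raise ValueError("labels length must equal tensor length")

        wt = init_weights(p, l, self.seed, self.weight_init)
        trace = np.zeros(self.epochs)
        omegas = np.zeros((n, p, l))
        omegas[np.arange(n), yi, :] = 1.0
        sign = 1.0 if self.error_sign == "output_minus_target" else -1.0
        step = self.eta * self.mu / n
        for epoch in range(self.epochs):
            sq_sum = 0.0
            bits_on = 0
            for i in range(n):
                F = values[i] * wt
                B = (F > self.delta).astype(float)
                E = sign * (B - omegas[i])
                wt = wt + step * wt * E
                sq_sum += float((E * E).mean())
                bits_on += int(B.sum())
            trace[epoch] = sq_sum / n
            logger.debug(
                "epoch %d: mse=%.6f bits_on=%d", epoch, trace[epoch], bits_on
            )

        self.classes_ = np.asarray(class_set)
        self.weights_ = wt
        self.mse_trace_ = trace
        self.classifier_ids_ = ids
        self.n_features_in_ = p * l
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Per-class bit counts, shape (n, p)."""
        check_is_fitted(self, "weights_")
        values, _, _, _ = self._coerce(X)
        F = values * self.weights_[None]
        return (F > self.delta).sum(axis=2)

    def predict_with_diagnostics(self, X):
        """Predict labels plus the fallback stage that decided each instance.

        Stage order: (0) per-class bit counts — used when the maximum is
        nonzero and unique; (1) per-class summed activations — used when the
        maximum is strictly positive and unique; (2) majority vote of the
        base classifiers' argmaxes — used when the mode is unique;
        (3) the lowest class index. Requiring a strictly positive unique
        maximum in stages 0-1 keeps the chain closed over the base
        classifiers' own predictions even with signed weights.
        """
        check_is_fitted(self, "weights_")
        values, _, class_set, _ = self._coerce(X)
        if values.shape[1:] != self.weights_.shape:
            raise ValueError(
                f"tensor slice shape {values.shape[1:]} does not match "
                f"trained weights {self.weights_.shape}"
            )
        n, p, l = values.shape
        F = values * self.weights_[None]
        bit_counts = (F > self.delta).sum(axis=2)
        act_sums = F.sum(axis=2)
        votes = np.zeros((n, p), dtype=int)
        arg = values.argmax(axis=1)  # (n, l), lowest-index ties
        for j in range(l):
            votes[np.arange(n), arg[:, j]] += 1

        out = np.zeros(n, dtype=int)
        stage = np.full(n, 3, dtype=np.int8)
        for scores, st, positive in (
            (bit_counts, 0, 1.0),
            (act_sums, 1, np.finfo(float).tiny),
            (votes, 2, 1),
        ):
            undecided = stage == 3
            if not undecided.any():
                break
            s = scores[undecided]
            smax = s.max(axis=1)
            unique = (s == smax[:, None]).sum(axis=1) == 1
            ok = unique & (smax >= positive)
            idx = np.flatnonzero(undecided)[ok]
            out[idx] = s[ok].argmax(axis=1)
            stage[idx] = st
        labels = self.classes_[out]
        return labels, stage

    def predict(self, X):
        return self.predict_with_diagnostics(X)[0]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "config": self.config.__dict__,
            "weights": self.weights_.tolist(),
            "mse_trace": self.mse_trace_.tolist(),
            "class_set": list(self.classes_.tolist()),
            "classifier_ids": list(self.classifier_ids_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BitFusionCombiner":
        obj = cls(**d["config"])
        obj.weights_ = np.asarray(d["weights"], dtype=float)
        obj.mse_trace_ = np.asarray(d["mse_trace"], dtype=float)
        obj.classes_ = np.asarray(d["class_set"])
        obj.classifier_ids_ = tuple(d["classifier_ids"])
        obj.n_features_in_ = obj.weights_.size
        return obj


#: A fitted :class:`BitFusionCombiner` is the package's fusion-model object.
FusionModel = BitFusionCombiner


def train(xi: SupportTensor, labels, config: FusionConfig) -> BitFusionCombiner:
    """Fit a :class:`BitFusionCombiner` on a training support tensor."""
    return BitFusionCombiner.from_config(config).fit(xi, labels)


def predict_fused(model: BitFusionCombiner, xi):
    """Predict labels for a support tensor; returns (labels, stage array).

    The stage array indexes :data:`FALLBACK_STAGES` per instance.
    """
    return model.predict_with_diagnostics(xi)
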