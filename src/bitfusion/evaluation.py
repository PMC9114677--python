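"""k-fold cross-validated benchmarking and the accuracy-gain statistic.

The protocol: split the dataset into k (default 10) folds; per fold, fit
the preprocessing (min-max + PCA) and the base-classifier layer on the
training part only, build an out-of-fold support tensor for combiner
training and a held-out tensor for scoring, then score every requested
fusion method on the held-out fold. Errors are reported as percentages.

The accuracy gain compares the fused model with the best single base
classifier: per fold, Acc_j = (P_j - S_j) / m with P_j and S_j the correct
counts of the fused model and the best classifier on the fold's m
instances; the dataset's gain is the mean of the Acc_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .base_ensemble import build_xi, default_specs
from .baselines import BASELINE_METHODS, BaselineCombiner
from .fusion import BitFusionCombiner, FusionConfig
from .io import Dataset
from .preprocessing import MinMaxNormalizer, PCATransform

__all__ = [
    "CVResult",
    "GainResult",
    "kfold_split",
    "error_rate",
    "cross_validate",
    "accuracy_gain",
    "aggregate_gain",
    "compute_gain",
    "ALL_METHODS",
]

ALL_METHODS = ("bitfusion",) + BASELINE_METHODS


@dataclass
class CVResult:
    """Cross-validation outcome for one dataset.

    ``per_fold_error`` maps each method to its k per-fold error percentages;
    ``per_method`` to their means. ``base_per_fold_correct`` /
    ``per_fold_correct`` carry the correct-prediction counts needed by the
    gain statistic, and ``manifest`` records every seed and resolved
    configuration of the run.
    """

    fold_assignments: np.ndarray
    per_fold_error: dict
    per_method: dict
    seed: int
    fold_sizes: np.ndarray
    per_fold_correct: dict
    base_per_fold_correct: dict
    base_errors: dict
    fallback_stage_counts: np.ndarray
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for method, errs in self.per_fold_error.items():
            mean = float(np.mean(errs))
            if abs(mean - self.per_method[method]) > 1e-10:
                raise ValueError(f"average error mismatch for {method!r}")


@dataclass
class GainResult:
    """Per-fold and mean accuracy gain versus a comparator method."""

    per_fold_gain: np.ndarray
    mean_gain: float
    comparator: str

    def __post_init__(self) -> None:
        self.per_fold_gain = np.asarray(self.per_fold_gain, dtype=float)
        if np.any(np.abs(self.per_fold_gain) > 1 + 1e-12):
            raise ValueError("per-fold gains must lie in [-1, 1]")
        if abs(self.mean_gain - self.per_fold_gain.mean()) > 1e-10:
            raise ValueError("mean gain must equal the fold mean")


def kfold_split(n: int, k: int, labels=None, stratified: bool = True,
                seed: int = 0) -> np.ndarray:
    """Fold assignment (values 0..k-1) for n instances.

    Stratified splitting preserves per-fold class proportions within one
    instance per class; it degrades to an unstratified split with a warning
    when some class has fewer than k instances.
    """
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n (got k={k}, n={n})")
    splitter = None
    if stratified and labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            warnings.warn(
                "a class has fewer instances than k folds; "
                "falling back to an unstratified split",
                UserWarning,
                stacklevel=2,
            )
        else:
            splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
    if splitter is None:
        splitter = KFold(k, shuffle=True, random_state=seed)
        labels = None
    X_dummy = np.zeros((n, 1))
    assign = np.empty(n, dtype=int)
    args = (X_dummy, labels) if labels is not None else (X_dummy,)
    for f, (_, test_idx) in enumerate(splitter.split(*args)):
        assign[test_idx] = f
    return assign


def error_rate(predicted, actual) -> float:
    """Misclassification percentage: 100 * #mismatches / n."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must have equal nonzero length")
    return 100.0 * float(np.mean(predicted != actual))


def accuracy_gain(correct_proposed: int, correct_best: int,
                  fold_size: int) -> float:
    """Per-fold gain Acc_j = (P_j - S_j) / m."""
    if fold_size < 1:
        raise ValueError("fold size must be >= 1")
    if not 0 <= correct_proposed <= fold_size:
        raise ValueError("P_j must lie in [0, fold size]")
    if not 0 <= correct_best <= fold_size:
        raise ValueError("S_j must lie in [0, fold size]")
    return (correct_proposed - correct_best) / fold_size


def aggregate_gain(per_fold: list[tuple[int, int, int]],
                   comparator: str = "best_base") -> GainResult:
    """Fold-wise (P_j, S_j, m_j) triples -> mean accuracy gain."""
    gains = np.array([accuracy_gain(*t) for t in per_fold])
    return GainResult(gains, float(gains.mean()), comparator)


def cross_validate(
    dataset: Dataset,
    methods=("bitfusion", "majority"),
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    base_specs=None,
    fusion_config: FusionConfig | None = None,
    normalize: bool = True,
    pca_retain=0.95,
    pca_center: bool = True,
    stacking: str = "out_of_fold",
    mode: str = "soft",
    ds_uncertainty: float = 0.1,
) -> CVResult:
    """Run the full fusion benchmark under k-fold cross-validation.

    Preprocessing and base-classifier fitting are confined to each training
    fold (no leakage); the combiner is trained on out-of-fold supports by
    default. ``pca_retain=None`` disables PCA. The default fusion
    configuration is :meth:`FusionConfig.trainable` seeded from ``seed``.
    """
    methods = tuple(methods)
    for mth in methods:
        if mth not in ALL_METHODS:
            raise ValueError(
                f"unknown fusion method {mth!r}; choose from {ALL_METHODS}"
            )
    if base_specs is None:
        base_specs = default_specs(seed)
    if fusion_config is None:
        fusion_config = FusionConfig.trainable(seed=seed)

    assign = kfold_split(dataset.n, k, dataset.labels, stratified, seed)
    per_fold_error = {mth: [] for mth in methods}
    per_fold_correct = {mth: [] for mth in methods}
    n_base = len(base_specs)
    base_correct = {j: [] for j in range(n_base)}
    fold_sizes = np.zeros(k, dtype=int)
    stage_counts = np.zeros(4, dtype=int)

    for f in range(k):
        test_mask = assign == f
        train_ds = dataset.subset(~test_mask)
        test_ds = dataset.subset(test_mask)
        fold_sizes[f] = test_ds.n
        if len(np.unique(train_ds.labels)) < 2:
            raise ValueError(f"fold {f}: training part has a single class")

        Xtr, Xte = train_ds.features, test_ds.features
        if normalize:
            norm = MinMaxNormalizer().fit(Xtr)
            Xtr, Xte = norm.transform(Xtr), norm.transform(Xte)
        if pca_retain is not None:
            pca = PCATransform(retain=pca_retain, center=pca_center).fit(Xtr)
            Xtr, Xte = pca.transform(Xtr), pca.transform(Xte)
        train_proc = Dataset(Xtr, train_ds.labels, dataset.class_set)
        test_proc = Dataset(Xte, test_ds.labels, dataset.class_set)

        xi_train = build_xi(base_specs, train_proc, train_proc, mode, stacking)
        xi_test = build_xi(
            base_specs, train_proc, test_proc, mode, "resubstitution"
        )

        y_test = test_ds.labels
        arg = xi_test.values.argmax(axis=1)
        class_arr = np.asarray(dataset.class_set)
        for j in range(n_base):
            base_correct[j].append(int((class_arr[arg[:, j]] == y_test).sum()))

        for mth in methods:
            if mth == "bitfusion":
                comb = BitFusionCombiner.from_config(fusion_config)
                comb.fit(xi_train, train_ds.labels)
                pred, stages = comb.predict_with_diagnostics(xi_test)
                stage_counts += np.bincount(stages, minlength=4)
            else:
                comb = BaselineCombiner(mth, ds_uncertainty)
                comb.fit(xi_train, train_ds.labels)
                pred = comb.predict(xi_test)
            per_fold_error[mth].append(error_rate(pred, y_test))
            per_fold_correct[mth].append(int((pred == y_test).sum()))

    base_ids = [f"{s.kind}#{j}" for j, s in enumerate(base_specs)]
    base_errors = {
        base_ids[j]: 100.0 * (1.0 - np.sum(base_correct[j]) / dataset.n)
        for j in range(n_base)
    }
    manifest = {
        "seed": seed,
        "k": k,
        "stratified": stratified,
        "methods": list(methods),
        "base_specs": [
            {"kind": s.kind, "hyperparameters": s.hyperparameters,
             "seed": s.seed}
            for s in base_specs
        ],
        "fusion_config": fusion_config.__dict__,
        "normalize": normalize,
        "pca_retain": pca_retain,
        "pca_center": pca_center,
        "stacking": stacking,
        "mode": mode,
        "ds_uncertainty": ds_uncertainty,
    }
    return CVResult(
        fold_assignments=assign,
        per_fold_error=per_fold_error,
        per_method={m: float(np.mean(v)) for m, v in per_fold_error.items()},
        seed=seed,
        fold_sizes=fold_sizes,
        per_fold_correct={m: np.array(v) for m, v in per_fold_correct.items()},
        base_per_fold_correct={
            base_ids[j]: np.array(base_correct[j]) for j in range(n_base)
        },
        base_errors=base_errors,
        fallback_stage_counts=stage_counts,
        manifest=manifest,
    )


def compute_gain(result: CVResult, method: str = "bitfusion") -> GainResult:
    """Accuracy gain of ``method`` over the best single base classifier.

    The comparator is the base classifier with the lowest cross-validated
    error over the whole run (its identity is recorded on the result).
    """
    if method not in result.per_fold_correct:
        raise ValueError(f"method {method!r} not present in the CV result")
    best = min(result.base_errors, key=result.base_errors.get)
    P = result.per_fold_correct[method]
    S = result.base_per_fold_correct[best]
    triples = [
        (int(p), int(s), int(m))
        for p, s, m in zip(P, S, result.fold_sizes)
    ]
    return aggregate_gain(triples, comparator=best)
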