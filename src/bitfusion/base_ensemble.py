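"""The base-classifier layer: five diverse learners and their support tensor.

Each base classifier emits, per instance, a soft class-support vector in
[0,1]^p that sums to 1 (its ``predict_proba``-style output with columns
reordered to the dataset's class order). Stacking l such classifiers over n
instances gives the support tensor xi of shape (n, p, l) — the sole input of
the fusion combiners.

The five default learners are naive Bayes, a CART decision tree, an
RBF-kernel SVM, 10-nearest-neighbours, and a one-hidden-layer MLP; all are
scikit-learn estimators behind a thin spec/ordering layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import Dataset

__all__ = [
    "BaseClassifierSpec",
    "SupportTensor",
    "default_specs",
    "fit_base",
    "predict_soft",
    "build_xi",
    "hard_from_soft",
]

KINDS = ("naive_bayes", "decision_tree", "svm_rbf", "knn", "mlp")

# RBF-SVM tuning grids used when grid_search is requested
SVM_C_GRID = [2.0**e for e in range(-5, 6)]
SVM_GAMMA_GRID = [2.0**e for e in range(-15, 0)]


@dataclass
class BaseClassifierSpec:
    """Declarative description of one base classifier.

    ``hyperparameters`` keys by kind:
      knn: ``k`` (default 10);
      svm_rbf: ``C`` (1.0), ``gamma`` ("scale"), ``grid_search`` (False);
      mlp: ``eta`` (0.4), ``mu`` (0.5), ``hidden_units`` (None =
      max(4, ceil((m+p)/2))), ``max_iter`` (500);
      decision_tree: ``max_depth`` (None), ``criterion`` ("gini").
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        hp = self.hyperparameters
        if self.kind == "knn" and hp.get("k", 10) < 1:
            raise ValueError("knn.k must be >= 1")
        if self.kind == "svm_rbf":
            if hp.get("C", 1.0) <= 0:
                raise ValueError("svm.C must be > 0")
            g = hp.get("gamma", "scale")
            if not isinstance(g, str) and g <= 0:
                raise ValueError("svm.gamma must be > 0")


def default_specs(seed: int = 0) -> list[BaseClassifierSpec]:
    """The five-classifier ensemble with per-classifier derived seeds."""
    return [
        BaseClassifierSpec("naive_bayes", {}, seed),
        BaseClassifierSpec("decision_tree", {}, seed + 1),
        BaseClassifierSpec("svm_rbf", {}, seed + 2),
        BaseClassifierSpec("knn", {"k": 10}, seed + 3),
        BaseClassifierSpec("mlp", {}, seed + 4),
    ]


@dataclass
class SupportTensor:
    """Per-instance, per-classifier class supports, shape (n, p, l).

    ``values[i, :, j]`` is classifier j's support vector for instance i over
    ``class_set``. Soft slices sum to 1; hard slices are one-hot.
    """

    values: np.ndarray
    mode: str
    class_set: tuple
    classifier_ids: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_set = tuple(self.class_set)
        self.classifier_ids = tuple(self.classifier_ids)
        if self.mode not in ("soft", "hard"):
            raise ValueError("mode must be 'soft' or 'hard'")
        if self.values.ndim != 3:
            raise ValueError("support tensor must have shape (n, p, l)")
        n, p, l = self.values.shape
        if p != len(self.class_set):
            raise ValueError("class axis length does not match class_set")
        if l != len(self.classifier_ids):
            raise ValueError("classifier axis length mismatch")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("support values must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if self.mode == "soft":
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("soft support slices must sum to 1")
        else:
            onehot = np.isin(self.values, (0.0, 1.0)).all()
            if not onehot or not np.allclose(sums, 1.0):
                raise ValueError("hard support slices must be one-hot")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def l(self) -> int:
        return self.values.shape[2]

    def argmax_labels(self) -> np.ndarray:
        """Per-classifier crisp predictions, shape (n, l), lowest-index ties."""
        return self.values.argmax(axis=1)


def hard_from_soft(values: np.ndarray) -> np.ndarray:
    """Project soft supports to one-hot via the maximum-membership rule.

    Ties go to the lowest class index (argmax convention).
    """
    values = np.asarray(values, dtype=float)
    win = values.argmax(axis=1)
    hard = np.zeros_like(values)
    n_idx, l_idx = np.meshgrid(
        np.arange(values.shape[0]), np.arange(values.shape[2]), indexing="ij"
    )
    hard[n_idx, win, l_idx] = 1.0
    return hard


class BaseModel:
    """Fitted base classifier plus the class-order bookkeeping.

    The wrapped estimator is trained on integer label indices into the
    dataset's ``class_set`` (first-appearance order); ``predict_soft``
    scatters its probability columns back onto the full class axis, so a
    class absent from the training rows simply receives zero support.
    """

    def __init__(self, spec: BaseClassifierSpec, estimator, class_set: tuple):
        self.spec = spec
        self.estimator = estimator
        self.class_set = tuple(class_set)

    def predict_soft(self, features: np.ndarray) -> np.ndarray:
        """Soft supports (rows sum to 1) over class_set order."""
        features = np.asarray(features, dtype=float)
        proba = self.estimator.predict_proba(features)
        full = np.zeros((features.shape[0], len(self.class_set)))
        full[:, np.asarray(self.estimator.classes_, dtype=int)] = proba
        # guard against tiny numerical drift outside [0,1]
        full = np.clip(full, 0.0, 1.0)
        return full / full.sum(axis=1, keepdims=True)

    def predict_hard(self, features: np.ndarray) -> np.ndarray:
        """Crisp class indices = argmax of the soft supports."""
        return self.predict_soft(features).argmax(axis=1)


def _make_estimator(spec: BaseClassifierSpec, m: int, p: int):
    hp = spec.hyperparameters
    if spec.kind == "naive_bayes":
        return GaussianNB()
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(
            criterion=hp.get("criterion", "gini"),
            max_depth=hp.get("max_depth"),
            random_state=spec.seed,
        )
    if spec.kind == "svm_rbf":
        return SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            probability=True,
            random_state=spec.seed,
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 10))
    # mlp: one hidden layer; width defaults to max(4, ceil((m+p)/2))
    hidden = hp.get("hidden_units") or max(4, math.ceil((m + p) / 2))
    return MLPClassifier(
        hidden_layer_sizes=(hidden,),
        learning_rate_init=hp.get("eta", 0.4),
        momentum=hp.get("mu", 0.5),
        max_iter=hp.get("max_iter", 500),
        random_state=spec.seed,
    )


def fit_base(spec: BaseClassifierSpec, train: Dataset) -> BaseModel:
    """Fit one base classifier on a training dataset.

    For the RBF SVM, ``hyperparameters["grid_search"]=True`` tunes (C, gamma)
    over C in 2^-5..2^5 and gamma in 2^-15..2^-1 by inner stratified CV; a
    class too small for the inner folds degrades to a plain fit with a
    warning.
    """
    if train.n < 1:
        raise ValueError("empty training set")
    y = train.label_indices()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    est = _make_estimator(spec, train.m, train.p)

    if spec.kind == "svm_rbf" and spec.hyperparameters.get("grid_search"):
        folds = int(spec.hyperparameters.get("inner_cv", 3))
        counts = np.bincount(y)
        if counts[counts > 0].min() < folds:
            warnings.warn(
                "a class has fewer instances than the inner-CV folds; "
                "fitting SVM without grid search",
                UserWarning,
                stacklevel=2,
            )
        else:
            est = GridSearchCV(
                est,
                {"C": SVM_C_GRID, "gamma": SVM_GAMMA_GRID},
                cv=StratifiedKFold(folds, shuffle=True, random_state=spec.seed),
                n_jobs=None,
            )
    with warnings.catch_warnings():
        # small folds can stop the MLP before full convergence; not an error
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        warnings.filterwarnings(
            "ignore", message=".*`probability` parameter was deprecated.*"
        )
        est.fit(train.features, y)
    if isinstance(est, GridSearchCV):
        est = est.best_estimator_
    return BaseModel(spec, est, train.class_set)


def predict_soft(model: BaseModel, features: np.ndarray) -> np.ndarray:
    """Soft support slice (n, p) for one fitted base model."""
    if not hasattr(model, "estimator"):
        raise ValueError("model is not a fitted BaseModel")
    return model.predict_soft(features)


def build_xi(
    specs: list[BaseClassifierSpec],
    train: Dataset,
    target: Dataset,
    mode: str = "soft",
    stacking: str = "out_of_fold",
) -> SupportTensor:
    """Assemble the support tensor xi of shape (target.n, p, l).

    When ``target is train`` and ``stacking="out_of_fold"``, each training
    instance's supports come from models fit on the other folds of an
    internal 5-fold stratified split (the standard stacking construction,
    avoiding the optimism of resubstitution outputs).
    """
    if len(specs) < 1:
        raise ValueError("need at least one base classifier spec")
    if stacking not in ("out_of_fold", "resubstitution"):
        raise ValueError(f"unknown stacking mode {stacking!r}")
    missing = set(target.class_set) - set(train.class_set)
    if missing:
        raise ValueError(f"classes {sorted(map(str, missing))} absent from train")
    if tuple(target.class_set) != tuple(train.class_set):
        target = Dataset(
            target.features, target.labels, train.class_set,
            target.feature_names,
        )

    n, p, l = target.n, train.p, len(specs)
    values = np.zeros((n, p, l))
    same = target is train or (
        target.n == train.n
        and np.array_equal(target.features, train.features)
        and np.array_equal(target.labels, train.labels)
    )
    if stacking == "out_of_fold" and same:
        y = train.label_indices()
        k = min(5, np.bincount(y).min())
        if k < 2:
            raise ValueError(
                "out-of-fold stacking needs >= 2 instances per class"
            )
        skf = StratifiedKFold(k, shuffle=True, random_state=specs[0].seed)
        for fit_idx, oof_idx in skf.split(train.features, y):
            sub = train.subset(fit_idx)
            for j, spec in enumerate(specs):
                model = fit_base(spec, sub)
                values[oof_idx, :, j] = model.predict_soft(
                    train.features[oof_idx]
                )
    else:
        for j, spec in enumerate(specs):
            model = fit_base(spec, train)
            values[:, :, j] = model.predict_soft(target.features)

    if mode == "hard":
        values = hard_from_soft(values)
    ids = tuple(f"{s.kind}#{j}" for j, s in enumerate(specs))
    return SupportTensor(values, mode, train.class_set, ids)
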