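"""End-to-end estimator: feature table in, fused class predictions out.

Chains the preprocessing (min-max, PCA), the five-classifier base layer and
the bit-fusion combiner into one scikit-learn classifier, so the whole
method composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .base_ensemble import SupportTensor, build_xi, default_specs, fit_base
from .fusion import BitFusionCombiner, FusionConfig
from .io import Dataset
from .preprocessing import MinMaxNormalizer, PCATransform

__all__ = ["BitFusionEnsembleClassifier"]


class BitFusionEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Bit-fusion ensemble over the five standard base classifiers.

    Parameters
    ----------
    base_specs : list of BaseClassifierSpec, optional
        Base layer; defaults to the five-classifier ensemble seeded from
        ``seed``.
    fusion_config : FusionConfig, optional
        Combiner hyperparameters; defaults to the trainable preset seeded
        from ``seed``.
    normalize : bool, default True
        Min-max scale features to [0, 1] (fit on training data only).
    pca_retain : int, float or None, default 0.95
        PCA retention (None disables PCA).
    pca_center : bool, default True
        Mean-center before the PCA scatter matrix.
    stacking : {"out_of_fold", "resubstitution"}, default "out_of_fold"
        How the combiner's training supports are produced.
    seed : int, default 0
        Master seed for derived defaults.
    """

    def __init__(self, base_specs=None, fusion_config=None,
                 normalize: bool = True, pca_retain=0.95,
                 pca_center: bool = True, stacking: str = "out_of_fold",
                 seed: int = 0):
        self.base_specs = base_specs
        self.fusion_config = fusion_config
        self.normalize = normalize
        self.pca_retain = pca_retain
        self.pca_center = pca_center
        self.stacking = stacking
        self.seed = seed

    def _as_dataset(self, X, y) -> Dataset:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        class_set = tuple(dict.fromkeys(y.tolist()))  # first appearance
        return Dataset(X, y, class_set)

    def fit(self, X, y):
        specs = self.base_specs or default_specs(self.seed)
        config = self.fusion_config or FusionConfig.trainable(seed=self.seed)
        data = self._as_dataset(X, y)

        feats = data.features
        self.normalizer_ = None
        if self.normalize:
            self.normalizer_ = MinMaxNormalizer().fit(feats)
            feats = self.normalizer_.transform(feats)
        self.pca_ = None
        if self.pca_retain is not None:
            self.pca_ = PCATransform(self.pca_retain, self.pca_center).fit(feats)
            feats = self.pca_.transform(feats)
        proc = Dataset(feats, data.labels, data.class_set)

        xi_train = build_xi(specs, proc, proc, "soft", self.stacking)
        self.base_models_ = [fit_base(s, proc) for s in specs]
        self.combiner_ = BitFusionCombiner.from_config(config)
        self.combiner_.fit(xi_train, proc.labels)
        self.classes_ = np.asarray(data.class_set)
        self.n_features_in_ = data.m
        return self

    def _support_tensor(self, X) -> SupportTensor:
        check_is_fitted(self, "combiner_")
        feats = np.asarray(X, dtype=float)
        if self.normalizer_ is not None:
            feats = self.normalizer_.transform(feats)
        if self.pca_ is not None:
            feats = self.pca_.transform(feats)
        values = np.stack(
            [m.predict_soft(feats) for m in self.base_models_], axis=2
        )
        ids = tuple(
            f"{m.spec.kind}#{j}" for j, m in enumerate(self.base_models_)
        )
        return SupportTensor(values, "soft", tuple(self.classes_.tolist()), ids)

    def predict(self, X):
        return self.combiner_.predict(self._support_tensor(X))

    def predict_with_diagnostics(self, X):
        """Labels plus the per-instance fallback stage (see combiner docs)."""
        return self.combiner_.predict_with_diagnostics(self._support_tensor(X))
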