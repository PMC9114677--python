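"""Synthetic fixtures: Gaussian-mixture feature tables and support tensors.

Two generators cover the two stages of the pipeline. The feature-table
generator emulates the flat numeric benchmark tables the method targets:
isotropic unit-variance Gaussian clusters whose centroids sit on a regular
simplex, so a single ``separation`` knob (inter-centroid distance in
within-class standard deviations) controls difficulty. The support-tensor
generator bypasses the base classifiers entirely and simulates their soft
outputs with controllable per-classifier accuracy and error correlation —
the natural fixture for studying the combiner in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_ensemble import SupportTensor
from .io import Dataset

__all__ = ["SyntheticSpec", "make_gaussian_dataset", "make_synthetic_xi"]

# Dirichlet concentration of soft slices: the winning class gets 10, every
# other class 1 — realistically peaked supports (winner mass ~10/(p+9)).
_WINNER_ALPHA = 10.0
_OTHER_ALPHA = 1.0


@dataclass
class SyntheticSpec:
    """Parameters shared by the two generators.

    ``separation`` is the pairwise centroid distance in units of the
    within-class standard deviation; ``base_accuracies`` (length l, each in
    (0, 1], and above chance 1/p for any fusion-learning use) are marginal
    argmax accuracies; ``correlation`` in [0, 1] is the probability that a
    classifier's error coin is the shared latent coin rather than its own,
    making classifiers err together.
    """

    n_instances: int = 300
    n_classes: int = 3
    n_features: int = 5
    n_classifiers: int = 5
    separation: float = 8.0
    base_accuracies: tuple = (0.7, 0.7, 0.7, 0.7, 0.7)
    correlation: float = 0.0
    mode: str = "soft"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if len(self.base_accuracies) != self.n_classifiers:
            raise ValueError("need one accuracy per classifier")
        for a in self.base_accuracies:
            if not 0 < a <= 1:
                raise ValueError("accuracies must lie in (0, 1]")
        if not 0 <= self.correlation <= 1:
            raise ValueError("correlation must lie in [0, 1]")


def _simplex_centroids(p: int, d: int, separation: float) -> np.ndarray:
    """p centroids, pairwise ``separation`` apart, embedded in R^d.

    The regular (p-1)-simplex needs p-1 dimensions; if d < p-1 the
    coordinates are truncated and the pairwise distances are only
    approximate.
    """
    # centered standard simplex from the identity's rows
    verts = np.eye(p) - 1.0 / p
    # orthonormal coordinates via SVD; nonzero singular directions = p-1
    _, s, vt = np.linalg.svd(verts, full_matrices=False)
    coords = verts @ vt.T[:, : p - 1]
    # rescale to the requested pairwise distance (currently sqrt(2))
    coords = coords * (separation / np.sqrt(2.0))
    out = np.zeros((p, d))
    take = min(d, p - 1)
    out[:, :take] = coords[:, :take]
    return out


def make_gaussian_dataset(spec: SyntheticSpec) -> Dataset:
    """Balanced isotropic Gaussian clusters on a simplex scaffold.

    Classes are interleaved (instance i belongs to class i mod p, sizes
    balanced within 1) and labelled ``c0 .. c{p-1}``; features are the class
    centroid plus unit-variance Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    p, d, n = spec.n_classes, spec.n_features, spec.n_instances
    centroids = _simplex_centroids(p, d, spec.separation)
    y = np.arange(n) % p
    features = centroids[y] + rng.standard_normal((n, d))
    labels = np.array([f"c{c}" for c in y])
    return Dataset(features, labels, tuple(f"c{c}" for c in range(p)))


def make_synthetic_xi(spec: SyntheticSpec, true_labels=None):
    """Simulated base-classifier support tensor; returns (tensor, labels).

    Per instance and classifier j, the slice's argmax is the true class
    with probability ``base_accuracies[j]`` and otherwise a uniformly chosen
    wrong class. Error coins: with probability ``correlation`` classifier j
    reuses the instance's shared latent uniform draw (so equally accurate
    classifiers err on the same instances); otherwise it flips its own.
    Soft slices are Dirichlet draws concentrated on the winner (10 vs 1),
    with the maximal component swapped onto the winner so the argmax
    guarantee is exact; hard slices are one-hot.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, l = spec.n_instances, spec.n_classes, spec.n_classifiers
    if true_labels is None:
        y = np.arange(n) % p
    else:
        y = np.asarray(true_labels, dtype=int)
        if len(y) != n or y.min() < 0 or y.max() >= p:
            raise ValueError("true_labels must be n class indices")

    values = np.zeros((n, p, l))
    for i in range(n):
        shared = rng.uniform()
        for j in range(l):
            coin = shared if rng.uniform() < spec.correlation else rng.uniform()
            if coin < spec.base_accuracies[j]:
                winner = y[i]
            else:
                wrong = rng.integers(p - 1)
                winner = wrong if wrong < y[i] else wrong + 1
            if spec.mode == "hard":
                values[i, winner, j] = 1.0
            else:
                alpha = np.full(p, _OTHER_ALPHA)
                alpha[winner] = _WINNER_ALPHA
                draw = rng.dirichlet(alpha)
                top = int(draw.argmax())
                if top != winner:
                    draw[top], draw[winner] = draw[winner], draw[top]
                values[i, :, j] = draw

    ids = tuple(f"sim#{j}" for j in range(l))
    tensor = SupportTensor(values, spec.mode, tuple(range(p)), ids)
    return tensor, y
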