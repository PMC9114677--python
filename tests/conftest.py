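"""Shared fixtures and the independent brute-force prediction oracle."""

import numpy as np
import pytest

from bitfusion import Dataset, SyntheticSpec, make_gaussian_dataset


def brute_force_predict(xi_values, wt, delta):
    """Scalar triple-loop re-implementation of the fused decision rule.

    Written independently of the package's vectorized path: explicit loops
    over classes and classifiers, explicit fallback chain. Returns
    (class indices, stage indices).
    """
    n = len(xi_values)
    preds, stages = [], []
    for i in range(n):
        sl = xi_values[i]
        p = len(sl)
        l = len(sl[0])
        # activation and bits by scalar loops
        bits = [[0] * l for _ in range(p)]
        acts = [[0.0] * l for _ in range(p)]
        for a in range(p):
            for b in range(l):
                acts[a][b] = sl[a][b] * wt[a][b]
                if acts[a][b] > delta:
                    bits[a][b] = 1
        # stage 0: per-class bit counts
        counts = [sum(bits[a]) for a in range(p)]
        choice, stage = _argmax_unique_positive(counts, minimum=1)
        if choice is None:
            sums = [sum(acts[a]) for a in range(p)]
            choice, _ = _argmax_unique_positive(sums, minimum=None)
            stage = 1
        else:
            stage = 0
        if choice is None:
            votes = [0] * p
            for b in range(l):
                best, best_v = 0, sl[0][b]
                for a in range(1, p):
                    if sl[a][b] > best_v:
                        best, best_v = a, sl[a][b]
                votes[best] += 1
            choice, _ = _argmax_unique_positive(votes, minimum=1)
            stage = 2
        if choice is None:
            choice, stage = 0, 3
        preds.append(choice)
        stages.append(stage)
    return np.array(preds), np.array(stages)


def _argmax_unique_positive(scores, minimum):
    best = max(scores)
    if minimum is not None and best < minimum:
        return None, None
    if minimum is None and best <= 0:
        return None, None
    winners = [i for i, s in enumerate(scores) if s == best]
    if len(winners) != 1:
        return None, None
    return winners[0], None


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Tiny 2-class, 2-feature dataset, linearly separable."""
    feats = np.array(
        [[-2.0, -1.5], [-1.8, -2.2], [-2.5, -1.0], [-1.2, -1.8],
         [2.0, 1.5], [1.8, 2.2], [2.5, 1.0], [1.2, 1.8]]
    )
    labels = np.array(["neg"] * 4 + ["pos"] * 4)
    return Dataset(feats, labels, ("neg", "pos"))


@pytest.fixture
def separable_dataset():
    """3-class well-separated Gaussian table (n=120, d=4)."""
    return make_gaussian_dataset(
        SyntheticSpec(
            n_instances=120, n_classes=3, n_features=4, separation=8.0, seed=7
        )
    )
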