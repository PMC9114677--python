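"""The bit-fusion combiner: every primitive against oracles and invariants."""

import numpy as np
import pytest
from sklearn.base import clone

from bitfusion import (
    BitFusionCombiner,
    FusionConfig,
    SupportTensor,
    binarize,
    forward,
    init_weights,
    instance_error,
    predict_fused,
    train,
    update_weights,
)
from conftest import brute_force_predict


class TestInitWeights:
    def test_deterministic_per_seed(self):
        a = init_weights(3, 5, seed=7)
        b = init_weights(3, 5, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, init_weights(3, 5, seed=8))

    def test_bounded_by_half(self):
        w = init_weights(4, 6, seed=0)
        assert np.abs(w).max() <= 0.5

    def test_uniform_mean_near_zero(self):
        w = init_weights(200, 500, seed=1)  # 1e5 entries
        assert abs(w.mean()) < 0.01

    def test_positive_init_in_upper_half(self):
        w = init_weights(4, 6, seed=0, weight_init="positive")
        assert w.min() >= 0.0 and w.max() <= 0.5

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            init_weights(1, 5, seed=0)


class TestForward:
    def test_identity_mask(self):
        wt = init_weights(3, 5, seed=0)
        np.testing.assert_array_equal(forward(np.ones((3, 5)), wt), wt)

    def test_one_hot_sparsity(self):
        xi = np.zeros((3, 2))
        xi[1, 0] = 1.0
        xi[2, 1] = 1.0
        F = forward(xi, np.full((3, 2), 0.3))
        assert F[1, 0] == 0.3 and F[2, 1] == 0.3
        assert np.count_nonzero(F) == 2

    def test_matches_scalar_double_loop(self, rng):
        xi = rng.uniform(0, 1, (3, 5))
        wt = rng.uniform(-0.5, 0.5, (3, 5))
        F = forward(xi, wt)
        for i in range(3):
            for j in range(5):
                assert abs(F[i, j] - xi[i, j] * wt[i, j]) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            forward(np.ones((3, 5)), np.ones((3, 4)))


class TestBinarize:
    def test_strictly_greater_than_threshold(self):
        F = np.array([[0.91, 0.9], [0.89, 1.0]])
        np.testing.assert_array_equal(
            binarize(F, 0.9), [[1, 0], [0, 1]]
        )

    def test_fresh_weights_cannot_cross_default_threshold(self, rng):
        """Supports <= 1 times weights <= 0.5 never exceed delta = 0.9."""
        xi = rng.uniform(0, 1, (4, 5))
        wt = init_weights(4, 5, seed=3)
        assert binarize(forward(xi, wt), 0.9).sum() == 0

    def test_monotone_in_delta(self, rng):
        F = rng.uniform(-1, 2, (6, 7))
        lo, hi = sorted(rng.uniform(0.05, 0.95, 2))
        assert np.all(binarize(F, hi) <= binarize(F, lo))

    def test_delta_range_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.ones((2, 2)), 1.5)


class TestInstanceError:
    def test_zero_bits_gives_minus_omega(self):
        E = instance_error(np.zeros((3, 4)), "b", ("a", "b", "c"))
        expected = np.zeros((3, 4))
        expected[1] = -1.0
        np.testing.assert_array_equal(E, expected)

    def test_perfect_bits_give_zero_error(self):
        B = np.zeros((3, 4))
        B[1] = 1.0
        np.testing.assert_array_equal(
            instance_error(B, "b", ("a", "b", "c")), 0.0
        )

    def test_entries_are_ternary(self, rng):
        B = rng.integers(0, 2, (4, 6)).astype(float)
        E = instance_error(B, 2, (0, 1, 2, 3))
        assert set(np.unique(E)) <= {-1.0, 0.0, 1.0}

    def test_target_minus_output_is_negated(self, rng):
        B = rng.integers(0, 2, (3, 5)).astype(float)
        a = instance_error(B, 0, (0, 1, 2), "output_minus_target")
        b = instance_error(B, 0, (0, 1, 2), "target_minus_output")
        np.testing.assert_array_equal(a, -b)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            instance_error(np.zeros((2, 2)), "z", ("a", "b"))


class TestUpdateWeights:
    def test_worked_example(self):
        wt = np.array([[0.4]])
        out = update_weights(wt, np.array([[1.0]]), eta=0.5, mu=0.2, n=10)
        assert out[0, 0] == pytest.approx(0.404, abs=1e-15)

    def test_zero_error_is_fixed_point(self, rng):
        wt = rng.uniform(-0.5, 0.5, (3, 5))
        np.testing.assert_array_equal(
            update_weights(wt, np.zeros((3, 5)), 0.71, 1e-5, 4), wt
        )

    def test_zero_weight_stays_zero(self):
        wt = np.zeros((2, 2))
        out = update_weights(wt, np.ones((2, 2)), 0.5, 0.5, 1)
        np.testing.assert_array_equal(out, 0.0)


def _random_tensor(rng, n, p, l):
    vals = rng.dirichlet(np.ones(p), size=(n, l)).transpose(0, 2, 1)
    return SupportTensor(
        vals, "soft", tuple(range(p)), tuple(f"c{j}" for j in range(l))
    )


class TestTraining:
    def test_bit_identical_across_runs(self, rng):
        xi = _random_tensor(rng, 30, 3, 5)
        y = rng.integers(0, 3, 30)
        cfg = FusionConfig.trainable(seed=11, epochs=20)
        m1 = train(xi, y, cfg)
        m2 = train(xi, y, cfg)
        np.testing.assert_array_equal(m1.weights_, m2.weights_)
        np.testing.assert_array_equal(m1.mse_trace_, m2.mse_trace_)

    def test_single_pass_matches_hand_computation(self):
        """epochs=1, n=1, one-hot xi: weights follow one explicit step."""
        vals = np.zeros((1, 2, 2))
        vals[0, 0, :] = 1.0  # both classifiers fully support class 0
        xi = SupportTensor(vals, "hard", (0, 1), ("a", "b"))
        cfg = FusionConfig(delta=0.5, eta=0.4, mu=0.3, epochs=1, seed=9)
        model = train(xi, [0], cfg)
        wt0 = init_weights(2, 2, seed=9)
        # hand: F = xi*wt0 (row 0 = wt0 row 0, row 1 = 0); B = F > 0.5
        B = (vals[0] * wt0 > 0.5).astype(float)
        omega = np.array([[1.0, 1.0], [0.0, 0.0]])
        E = B - omega
        expected = wt0 + 0.4 * wt0 * 0.3 * E / 1
        np.testing.assert_allclose(model.weights_, expected, atol=1e-15)
        assert model.mse_trace_[0] == pytest.approx((E * E).mean())

    def test_sign_preserved_under_default_config(self, rng):
        xi = _random_tensor(rng, 50, 3, 5)
        y = rng.integers(0, 3, 50)
        model = train(xi, y, FusionConfig(seed=2))  # eta*mu/n << 1
        signs0 = np.sign(init_weights(3, 5, seed=2))
        np.testing.assert_array_equal(np.sign(model.weights_), signs0)

    def test_mse_trace_finite_nonnegative(self, rng):
        xi = _random_tensor(rng, 20, 3, 4)
        model = train(xi, rng.integers(0, 3, 20),
                      FusionConfig.trainable(seed=0, epochs=15))
        assert model.mse_trace_.shape == (15,)
        assert np.all(np.isfinite(model.mse_trace_))
        assert np.all(model.mse_trace_ >= 0)

    def test_empty_tensor_rejected(self):
        xi = np.zeros((0, 3, 2))
        with pytest.raises(ValueError, match="empty"):
            BitFusionCombiner().fit(xi, [])

    def test_unknown_label_rejected(self, rng):
        xi = _random_tensor(rng, 5, 3, 2)
        with pytest.raises(ValueError, match="class set"):
            BitFusionCombiner().fit(xi, [0, 1, 2, 0, 9])


class TestPrediction:
    def _fitted(self, rng, p=3, l=5):
        xi = _random_tensor(rng, 20, p, l)
        y = rng.integers(0, p, 20)
        return train(xi, y, FusionConfig.trainable(seed=4, epochs=5))

    def test_bit_count_argmax(self, rng):
        model = self._fitted(rng)
        # craft a tensor whose bits are known: huge weights make supports
        # fire exactly where the support is large
        model.weights_ = np.zeros((3, 5))
        model.weights_[1, :3] = 10.0  # class 1 fires in 3 columns
        model.weights_[2, 3:] = 10.0  # class 2 fires in 2 columns
        vals = np.full((1, 3, 5), 1.0 / 3)
        xi = SupportTensor(vals, "soft", (0, 1, 2), model.classifier_ids_)
        labels, stages = predict_fused(model, xi)
        assert labels[0] == 1 and stages[0] == 0

    def test_all_zero_bits_fall_back_to_support_sum(self, rng):
        model = self._fitted(rng)
        model.weights_ = np.array(
            [[0.1, 0.0, 0.0, 0.0, 0.0],
             [0.4, 0.0, 0.0, 0.0, 0.0],
             [0.2, 0.0, 0.0, 0.0, 0.0]]
        )
        vals = np.zeros((1, 3, 5))
        vals[0, :, :] = 1.0 / 3
        xi = SupportTensor(vals, "soft", (0, 1, 2), model.classifier_ids_)
        labels, stages = predict_fused(model, xi)
        assert labels[0] == 1 and stages[0] == 1

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized fused decisions equal the scalar triple-loop oracle."""
        for _ in range(40):
            p = int(rng.integers(2, 6))
            l = int(rng.integers(1, 8))
            n = 5
            xi = _random_tensor(rng, n, p, l)
            model = BitFusionCombiner(epochs=1, seed=int(rng.integers(100)))
            model.fit(xi, rng.integers(0, p, n))
            model.weights_ = rng.uniform(-2, 2, (p, l))
            delta = float(rng.uniform(0.05, 0.95))
            model.delta = delta
            got_labels, got_stages = predict_fused(model, xi)
            exp_labels, exp_stages = brute_force_predict(
                xi.values.tolist(), model.weights_.tolist(), delta
            )
            np.testing.assert_array_equal(got_labels, exp_labels)
            np.testing.assert_array_equal(got_stages, exp_stages)

    def test_unanimity_in_hard_mode(self, rng):
        """A unanimous hard-mode ensemble is always returned verbatim."""
        for _ in range(100):
            p = int(rng.integers(2, 5))
            l = int(rng.integers(1, 7))
            c = int(rng.integers(0, p))
            vals = np.zeros((1, p, l))
            vals[0, c, :] = 1.0
            xi = SupportTensor(
                vals, "hard", tuple(range(p)),
                tuple(f"c{j}" for j in range(l)),
            )
            model = BitFusionCombiner(epochs=1, seed=0)
            model.fit(_random_tensor(rng, 4, p, l), rng.integers(0, p, 4))
            model.weights_ = rng.uniform(-0.5, 0.5, (p, l))
            labels, _ = predict_fused(model, xi)
            assert labels[0] == c

    def test_closure_in_hard_mode(self, rng):
        """Fused prediction is a base prediction or the stage-3 default."""
        for _ in range(100):
            p, l = 4, 5
            winners = rng.integers(0, p, l)
            vals = np.zeros((1, p, l))
            vals[0, winners, np.arange(l)] = 1.0
            xi = SupportTensor(
                vals, "hard", tuple(range(p)), tuple(f"c{j}" for j in range(l))
            )
            model = BitFusionCombiner(epochs=1, seed=0)
            model.fit(_random_tensor(rng, 4, p, l), rng.integers(0, p, 4))
            model.weights_ = rng.uniform(-3, 3, (p, l))
            labels, stages = predict_fused(model, xi)
            assert labels[0] in set(winners) or stages[0] == 3

    def test_shape_mismatch_rejected(self, rng):
        model = self._fitted(rng, p=3, l=5)
        xi = _random_tensor(rng, 4, 3, 4)
        with pytest.raises(ValueError, match="does not match"):
            model.predict(xi)


class TestEstimatorContract:
    def test_clone_and_params_round_trip(self):
        est = BitFusionCombiner(delta=0.8, eta=0.3, mu=0.1, epochs=7, seed=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_config_round_trip(self):
        cfg = FusionConfig.trainable(seed=5)
        est = BitFusionCombiner.from_config(cfg)
        assert est.config == cfg

    def test_serialization_round_trip(self, rng):
        xi = _random_tensor(rng, 15, 3, 4)
        y = rng.integers(0, 3, 15)
        model = train(xi, y, FusionConfig.trainable(seed=1, epochs=5))
        back = BitFusionCombiner.from_dict(model.to_dict())
        np.testing.assert_allclose(back.weights_, model.weights_)
        np.testing.assert_array_equal(back.predict(xi), model.predict(xi))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(delta=1.2)
        with pytest.raises(ValueError):
            FusionConfig(eta=-0.1)
        with pytest.raises(ValueError):
            FusionConfig(epochs=0)
        with pytest.raises(ValueError):
            FusionConfig(error_sign="banana")
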