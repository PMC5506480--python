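import numpy as np
import pytest

from annorbm import (
    RBMParams,
    TrainConfig,
    ValidationError,
    cd_update,
    energy,
    exact_gradient,
    exact_log_likelihood,
    exact_partition,
    prob_h_given_v,
    prob_v_given_h,
    train_rbm,
)
from annorbm.rbm import initial_params, train_rbm_sized

from conftest import random_params
from oracle_utils import conditional_h_given_v, conditional_v_given_h


class TestEnergy:
    def test_all_zero_state_has_zero_energy(self):
        rng = np.random.default_rng(0)
        params = random_params(rng, 3, 2)
        assert energy(np.zeros(3), np.zeros(2), params) == 0.0

    def test_hand_computed_value(self):
        params = RBMParams(W=[[1.0]], a=[0.5], b=[-0.25])
        assert energy(np.array([1.0]), np.array([1.0]), params) == pytest.approx(-1.25)

    def test_dimension_mismatch(self):
        params = RBMParams(W=[[1.0]], a=[0.5], b=[-0.25])
        with pytest.raises(ValidationError):
            energy(np.array([1.0, 0.0]), np.array([1.0]), params)

    @pytest.mark.parametrize("seed", range(5))
    def test_boltzmann_probabilities_normalise(self, seed):
        import itertools

        rng = np.random.default_rng(seed)
        params = random_params(rng, 3, 2)
        Z = exact_partition(params)
        total = sum(
            np.exp(-energy(np.array(v, float), np.array(h, float), params)) / Z
            for v in itertools.product((0, 1), repeat=3)
            for h in itertools.product((0, 1), repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestConditionals:
    def test_zero_params_give_half(self):
        params = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        v = np.array([[1.0, 0.0, 1.0]])
        assert np.allclose(prob_h_given_v(v, params), 0.5)
        assert np.allclose(prob_v_given_h(np.array([[1.0, 0.0]]), params), 0.5)

    def test_bias_weight_cancellation(self):
        params = RBMParams(W=[[2.0]], a=[0.0], b=[-2.0])
        assert prob_h_given_v(np.array([[1.0]]), params)[0, 0] == pytest.approx(0.5)

    def test_h_given_zero_hidden_is_sigma_a(self):
        rng = np.random.default_rng(1)
        params = random_params(rng, 4, 2)
        out = prob_v_given_h(np.zeros((1, 2)), params)
        assert np.allclose(out[0], 1 / (1 + np.exp(-params.a)))

    @pytest.mark.parametrize("seed", range(10))
    def test_agree_with_joint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, 3, 2)
        v = (rng.random(3) < 0.5).astype(float)
        h = (rng.random(2) < 0.5).astype(float)
        ours_h = prob_h_given_v(v, params)[0]
        oracle_h = conditional_h_given_v(params.W, params.a, params.b, v)
        assert np.abs(ours_h - oracle_h).max() < 1e-10
        ours_v = prob_v_given_h(h, params)[0]
        oracle_v = conditional_v_given_h(params.W, params.a, params.b, h)
        assert np.abs(ours_v - oracle_v).max() < 1e-10

    def test_no_overflow_at_extreme_inputs(self):
        params = RBMParams(W=[[500.0]], a=[-500.0], b=[500.0])
        out = prob_h_given_v(np.array([[1.0]]), params)
        assert 0 < out[0, 0] < 1
        out = prob_v_given_h(np.array([[1.0]]), params)
        assert 0 < out[0, 0] < 1


class TestCDUpdate:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        params = random_params(rng, 4, 3, scale=0.5)
        data = (rng.random((6, 4)) < 0.4).astype(float)
        return params, data

    def test_deltas_scale_linearly_with_learning_rate(self):
        params, data = self._setup()
        base = TrainConfig(learning_rate=0.01, weight_decay=0.0, dropout_rate=0.0)
        doubled = base.replace(learning_rate=0.02)
        d1 = cd_update(data, params, base, np.random.default_rng(5))
        d2 = cd_update(data, params, doubled, np.random.default_rng(5))
        for a, b in zip(d1, d2):
            assert np.allclose(2 * a, b)

    def test_deterministic_given_rng_state(self):
        params, data = self._setup()
        cfg = TrainConfig()
        d1 = cd_update(data, params, cfg, np.random.default_rng(7))
        d2 = cd_update(data, params, cfg, np.random.default_rng(7))
        for a, b in zip(d1, d2):
            assert np.array_equal(a, b)

    def test_empty_batch_is_an_error(self):
        params, _ = self._setup()
        with pytest.raises(ValidationError):
            cd_update(np.zeros((0, 4)), params, TrainConfig(), np.random.default_rng(0))

    def test_weight_decay_pulls_towards_zero(self):
        params, data = self._setup()
        plain = TrainConfig(weight_decay=0.0, dropout_rate=0.0)
        decayed = TrainConfig(weight_decay=0.1, dropout_rate=0.0)
        dW0, _, _ = cd_update(data, params, plain, np.random.default_rng(3))
        dW1, _, _ = cd_update(data, params, decayed, np.random.default_rng(3))
        # the decay contribution is exactly -eps * lambda * W
        assert np.allclose(dW1 - dW0, -plain.learning_rate * 0.1 * params.W)

    def test_mean_update_aligns_with_exact_gradient(self):
        rng = np.random.default_rng(11)
        params = random_params(rng, 4, 3, scale=0.5)
        data = (rng.random((20, 4)) < 0.4).astype(float)
        gW, _, _ = exact_gradient(data, params)
        cfg = TrainConfig(learning_rate=1.0, weight_decay=0.0, dropout_rate=0.0)
        acc = np.zeros_like(gW)
        sampler = np.random.default_rng(12)
        n = 2000
        for _ in range(n):
            dW, _, _ = cd_update(data, params, cfg, sampler)
            acc += dW
        acc /= n
        cos = (acc * gW).sum() / (np.linalg.norm(acc) * np.linalg.norm(gW))
        assert cos > 0.5


class TestTrainRBM:
    def test_zero_epochs_returns_initial_params(self):
        data = np.eye(4)
        cfg = TrainConfig(epochs=0, seed=3, init="gaussian")
        trained = train_rbm(data, cfg)
        rng = np.random.default_rng(3)
        init = initial_params(4, 2, cfg, rng)
        assert np.array_equal(trained.W, init.W)
        assert np.array_equal(trained.a, init.a)

    def test_same_seed_gives_identical_params(self):
        data = (np.random.default_rng(0).random((10, 5)) < 0.5).astype(float)
        cfg = TrainConfig(epochs=5, seed=42)
        p1 = train_rbm(data, cfg)
        p2 = train_rbm(data, cfg)
        assert np.array_equal(p1.W, p2.W)
        assert np.array_equal(p1.b, p2.b)

    def test_non_binary_data_is_an_error(self):
        with pytest.raises(ValidationError):
            train_rbm(np.full((3, 3), 0.5), TrainConfig())

    def test_cd_training_raises_exact_likelihood(self):
        rng = np.random.default_rng(99)
        patterns = rng.permutation(16)[:8]
        data = np.array([[(p >> i) & 1 for i in range(4)] for p in patterns], float)
        cfg = TrainConfig(
            learning_rate=0.05, epochs=500, batch_size=8, weight_decay=0.0,
            dropout_rate=0.0, init="gaussian", seed=1,
        )
        before = exact_log_likelihood(data, initial_params(4, 3, cfg, np.random.default_rng(1)))
        after = exact_log_likelihood(data, train_rbm_sized(data, 3, cfg))
        assert after > before


class TestExactOracles:
    def test_zero_params_partition_counts_states(self):
        params = RBMParams(np.zeros((2, 1)), np.zeros(2), np.zeros(1))
        assert exact_partition(params) == pytest.approx(8.0)

    def test_enumeration_guard(self):
        params = RBMParams(np.zeros((15, 10)), np.zeros(15), np.zeros(10))
        with pytest.raises(ValidationError, match="guard"):
            exact_partition(params)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, 3, 2, scale=0.7)
        data = (rng.random((6, 3)) < 0.5).astype(float)
        gW, ga, gb = exact_gradient(data, params)
        eps = 1e-5

        def ll(p):
            return exact_log_likelihood(data, p)

        for (i, j), g in np.ndenumerate(gW):
            up, dn = params.copy(), params.copy()
            up.W[i, j] += eps
            dn.W[i, j] -= eps
            assert g == pytest.approx((ll(up) - ll(dn)) / (2 * eps), abs=1e-6)
        for i, g in enumerate(ga):
            up, dn = params.copy(), params.copy()
            up.a[i] += eps
            dn.a[i] -= eps
            assert g == pytest.approx((ll(up) - ll(dn)) / (2 * eps), abs=1e-6)
        for j, g in enumerate(gb):
            up, dn = params.copy(), params.copy()
            up.b[j] += eps
            dn.b[j] -= eps
            assert g == pytest.approx((ll(up) - ll(dn)) / (2 * eps), abs=1e-6)

    def test_uniform_data_zero_params_gives_zero_gradient(self):
        import itertools

        data = np.array(list(itertools.product((0.0, 1.0), repeat=3)))
        params = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        gW, ga, gb = exact_gradient(data, params)
        assert np.allclose(gW, 0, atol=1e-12)
        assert np.allclose(ga, 0, atol=1e-12)
        assert np.allclose(gb, 0, atol=1e-12)

    def test_gradient_ascent_monotonically_improves_likelihood(self):
        rng = np.random.default_rng(5)
        patterns = rng.permutation(16)[:8]
        data = np.array([[(p >> i) & 1 for i in range(4)] for p in patterns], float)
        params = random_params(rng, 4, 3, scale=0.1)
        lls = [exact_log_likelihood(data, params)]
        for _ in range(200):
            gW, ga, gb = exact_gradient(data, params)
            params.W += 0.05 * gW
            params.a += 0.05 * ga
            params.b += 0.05 * gb
            lls.append(exact_log_likelihood(data, params))
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))
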