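import numpy as np
import pytest

from pinnode.losses import (LossState, data_loss, data_loss_grads, ode_loss,
                            ode_loss_grads, sample_collocation, total_loss)
from pinnode.nets import MLP, Adam
from pinnode.normalization import NormalizationSpec
from pinnode.systems import ODESystem


class TestDataLoss:
    def test_perfect_fit_is_zero(self):
        net = MLP([1, 1], np.random.default_rng(0))
        net.weights[0][:] = 0.0
        net.biases[0][:] = 0.4
        assert data_loss(net, [0.1, 0.5], np.full((2, 1), 0.4)) == pytest.approx(0.0)

    def test_single_unit_error(self):
        net = MLP([1, 1], np.random.default_rng(0))
        net.set_flat(np.zeros(net.n_params))
        assert data_loss(net, [0.0], np.array([[1.0]])) == pytest.approx(1.0)

    def test_hand_mean(self):
        net = MLP([1, 1], np.random.default_rng(0))
        net.set_flat(np.zeros(net.n_params))
        # squared normalized errors 0.04 and 0.16 -> mean 0.10
        obs = np.array([[0.2], [-0.4]])
        assert data_loss(net, [0.0, 0.5], obs) == pytest.approx(0.10)

    def test_empty_observations_rejected(self):
        net = MLP([1, 1], np.random.default_rng(0))
        with pytest.raises(ValueError):
            data_loss(net, [], np.empty((0, 1)))


def _zero_system():
    return ODESystem("zero", 1, rhs=lambda t, u, th: np.zeros_like(u),
                     jac_state=lambda t, u, th: np.zeros((u.shape[0], 1, 1)))


class TestOdeLoss:
    def test_zero_rhs_constant_net_is_zero(self):
        net = MLP([1, 4, 1], np.random.default_rng(0))
        net.weights[0][:] = 0.0  # constant output, zero derivative
        spec = NormalizationSpec(0, 2, [-1.0], [1.0])
        lf = ode_loss(net, _zero_system(), spec, np.linspace(-1, 1, 16))
        np.testing.assert_allclose(lf, 0.0, atol=1e-20)

    def test_regression_fit_of_exact_solution_has_small_residual(self, exp_system, exp_spec):
        """A surrogate fitted to the closed form e^-t by plain regression
        (no physics loss) satisfies the normalized ODE residual."""
        rng = np.random.default_rng(1)
        net = MLP.from_spec(4, 32, 1, 1, rng)
        tp = np.linspace(-1, 1, 256)
        t = exp_spec.denormalize_time(tp)
        target = exp_spec.normalize_state(np.exp(-t)[:, None])
        adam = Adam(2e-3)
        st = adam.init(net.n_params)
        params = net.get_flat()
        for _ in range(4000):
            y, cache = net.forward(tp[:, None], cache=True)
            g = MLP.flatten_grads(net.backward(cache, 2 * (y - target) / y.size))
            params = adam.update(st, params, g)
            net.set_flat(params)
        lf = ode_loss(net, exp_system, exp_spec, np.linspace(-0.99, 0.99, 200))
        assert lf[0] < 1e-3

    def test_gradients_match_finite_differences(self, exp_system, exp_spec):
        rng = np.random.default_rng(5)
        net = MLP([1, 5, 1], rng)
        tp = np.linspace(-0.9, 0.9, 8)
        lf, g = ode_loss_grads(net, exp_system, exp_spec, tp)
        flat0 = net.get_flat()
        for i in np.random.default_rng(0).choice(flat0.size, 12, replace=False):
            e = np.zeros_like(flat0)
            e[i] = 1e-6
            net.set_flat(flat0 + e)
            lp = ode_loss(net, exp_system, exp_spec, tp).sum()
            net.set_flat(flat0 - e)
            lm = ode_loss(net, exp_system, exp_spec, tp).sum()
            net.set_flat(flat0)
            assert g[i] == pytest.approx((lp - lm) / 2e-6, abs=1e-6, rel=1e-4)


class TestSampleCollocation:
    def test_points_stay_in_tiny_interval(self):
        rng = np.random.default_rng(0)
        pts = sample_collocation(50, (-1.0, -1.0 + 1e-6), rng)
        assert np.all(np.abs(pts + 1.0) < 1e-6)

    def test_mean_close_to_interval_center(self):
        rng = np.random.default_rng(1)
        pts = sample_collocation(10_000, (-1.0, 1.0), rng)
        assert abs(pts.mean()) < 0.03

    def test_same_seed_same_sample(self):
        a = sample_collocation(10, (0.0, 1.0), np.random.default_rng(7))
        b = sample_collocation(10, (0.0, 1.0), np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            sample_collocation(10, (1.0, 1.0), np.random.default_rng(0))


class TestLossCombination:
    def test_total_matches_weighted_combination(self):
        # L = L_data + (1/F) sum lambda_i L_f(i), to machine precision
        ld = 0.3
        lf = np.array([0.1, 0.4, 0.2])
        lam = np.array([2.0, 0.5, 1.0])
        expected = ld + (lam * lf).sum() / 3
        assert total_loss(ld, lf, lam) == expected
        assert LossState(ld, lf, lam).total == expected

    def test_lambda_one_default(self):
        assert total_loss(0.5, np.array([0.3])) == pytest.approx(0.8)

    def test_data_grads_padded_for_param_models(self):
        net = MLP([1, 3, 1], np.random.default_rng(0))
        _, g = data_loss_grads(net, [0.0], np.array([[0.5]]), n_extra=4)
        assert g.size == net.n_params + 4
        np.testing.assert_array_equal(g[-4:], 0.0)
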