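import numpy as np
import pytest

from pinnode.decomposition import (DecompositionPlan, handoff_data, partition,
                                   stitched_predict, train_decomposed)
from pinnode.nets import MLP
from pinnode.normalization import NormalizationSpec
from pinnode.simulate import ObservationSet
from pinnode.training import BalancingConfig, CollocationConfig, PhaseSchedule, train

from conftest import DESK_NET


class TestPartition:
    def test_benchmark_geometry(self):
        # 40 subdomains on [0, 20] with O=0.05: cores 0.5 wide, extended 0.6
        plan = partition((0.0, 20.0), 40, 0.05)
        assert plan.core(2) == pytest.approx((0.5, 1.0))
        ext = plan.extended(2)
        assert ext == pytest.approx((0.45, 1.05))
        assert ext[1] - ext[0] == pytest.approx(0.6)
        assert plan.core(1)[1] - plan.core(1)[0] == pytest.approx(0.5)

    def test_single_domain(self):
        plan = partition((0.0, 2.0), 1, 0.05)
        assert plan.n_subdomains == 1
        assert plan.extended(1) == (0.0, 2.0)  # clipped at both window ends

    def test_cores_tile_window(self):
        plan = partition((0.0, 20.0), 7, 0.1)
        widths = [plan.core(s)[1] - plan.core(s)[0] for s in range(1, 8)]
        assert sum(widths) == pytest.approx(20.0)

    def test_overlap_must_be_smaller_than_core(self):
        with pytest.raises(ValueError):
            partition((0.0, 2.0), 4, 0.6)


def _affine_net(w: float, b: float) -> MLP:
    net = MLP([1, 1], np.random.default_rng(0))
    net.weights[0][:] = w
    net.biases[0][:] = b
    return net


class TestHandoff:
    def test_even_spacing(self):
        spec = NormalizationSpec(0.0, 2.0, [0.0], [1.0])
        obs = handoff_data(_affine_net(0.0, 0.0), spec, (0.45, 0.5), 100)
        assert obs.n_obs == 100
        np.testing.assert_allclose(np.diff(obs.times), 0.05 / 99, atol=1e-12)

    def test_values_are_denormalized_predictions(self):
        # net outputs the normalized identity map: predictions recover t
        spec = NormalizationSpec(0.0, 2.0, [0.0], [2.0])
        obs = handoff_data(_affine_net(1.0, 0.0), spec, (0.5, 1.0), 11)
        np.testing.assert_allclose(obs.values[:, 0], obs.times, atol=1e-12)

    def test_interface_location(self):
        plan = partition((0.0, 20.0), 40, 0.05)
        assert plan.interface(2) == pytest.approx((0.5, 0.55))
        with pytest.raises(ValueError):
            plan.interface(1)  # first subdomain uses the user data condition


class TestStitchedPredict:
    def _two_domain_setup(self):
        plan = partition((0.0, 2.0), 2, 0.1)
        specs = [NormalizationSpec(0.0, 1.1, [0.0], [2.0]),
                 NormalizationSpec(0.9, 2.0, [0.0], [2.0])]
        nets = [_affine_net(0.0, -1.0), _affine_net(0.0, 1.0)]  # predict 0 / 2
        return plan, specs, nets

    def test_core_ownership_and_tie_break(self):
        plan, specs, nets = self._two_domain_setup()
        out = stitched_predict(nets, specs, plan, [0.5, 1.0, 1.5, 2.0])
        # boundary t=1.0 belongs to the *right* core (left-closed convention)
        np.testing.assert_allclose(out[:, 0], [0.0, 2.0, 2.0, 2.0])

    def test_out_of_window_rejected(self):
        plan, specs, nets = self._two_domain_setup()
        with pytest.raises(ValueError):
            stitched_predict(nets, specs, plan, [2.5])


class TestTrainDecomposed:
    CFG = dict(
        schedule=PhaseSchedule(100, 1500, 600, eval_every=200, patience=20),
        collocation=CollocationConfig(32),
        eval_points=100, **DESK_NET,
    )

    def test_single_subdomain_equals_plain_train(self, exp_system, exp_initial_obs):
        bounds = (np.array([np.exp(-2.0)]), np.array([1.0]))
        plan = partition((0.0, 2.0), 1, 0.05)
        nets, specs, _ = train_decomposed(
            exp_system, plan, exp_initial_obs, state_bounds=bounds, seed=5, **self.CFG)
        spec = NormalizationSpec(0.0, 2.0, bounds[0], bounds[1])
        net, _, _ = train(exp_system, exp_initial_obs, spec, (0.0, 2.0),
                          seed=5, balancing=BalancingConfig(), **self.CFG)
        np.testing.assert_array_equal(nets[0].get_flat(), net.get_flat())

    def test_decomposed_exponential_accuracy_and_continuity(self, exp_system):
        """Chained subdomains on [0, 4]: the stitched curve tracks e^-t and
        interface jumps stay bounded by the handoff-fit error scale."""
        obs = ObservationSet([0.0], [[1.0]])
        plan = partition((0.0, 4.0), 2, 0.2)
        nets, specs, _ = train_decomposed(
            exp_system, plan, obs,
            state_bounds=(np.array([np.exp(-4.0)]), np.array([1.0])),
            seed=1, **self.CFG)
        t = np.linspace(0, 4, 161)
        pred = stitched_predict(nets, specs, plan, t)
        rmse = np.sqrt(np.mean((pred[:, 0] - np.exp(-t)) ** 2))
        assert rmse < 0.05
        # continuity at the interface T1=2
        eps = 1e-6
        left = stitched_predict(nets, specs, plan, [2.0 - eps])[0, 0]
        right = stitched_predict(nets, specs, plan, [2.0 + eps])[0, 0]
        # handoff-fit error: how well net 2 reproduces its anchor data
        anchor = handoff_data(nets[0], specs[0], plan.interface(2), plan.handoff_points)
        tp = specs[1].normalize_time(anchor.times)
        fit = specs[1].denormalize_state(nets[1].forward(tp[:, None]))
        handoff_rmse = np.sqrt(np.mean((fit - anchor.values) ** 2))
        assert abs(left - right) <= max(10 * handoff_rmse, 1e-6)

    def test_determinism(self, exp_system, exp_initial_obs):
        bounds = (np.array([np.exp(-2.0)]), np.array([1.0]))
        plan = partition((0.0, 2.0), 2, 0.1)
        cfg = dict(self.CFG)
        cfg["schedule"] = PhaseSchedule(50, 400, 200, eval_every=100, patience=10)
        a = train_decomposed(exp_system, plan, exp_initial_obs,
                             state_bounds=bounds, seed=11, **cfg)
        b = train_decomposed(exp_system, plan, exp_initial_obs,
                             state_bounds=bounds, seed=11, **cfg)
        t = np.linspace(0, 2, 41)
        np.testing.assert_array_equal(
            stitched_predict(a[0], a[1], plan, t),
            stitched_predict(b[0], b[1], plan, t))
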