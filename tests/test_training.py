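import numpy as np
import pytest

from pinnode.normalization import NormalizationSpec
from pinnode.simulate import ObservationSet
from pinnode.training import (BalancingConfig, CollocationConfig, PhaseSchedule,
                              balance_lambdas, current_interval, evaluation_loss,
                              train)

from conftest import DESK_NET


class TestBalanceLambdas:
    def test_hand_ratio(self):
        # mean|(0.1,-0.3,0.2)| = 0.2; max|(2,-4,0)| = 4 -> lambda_hat = 0.05
        cfg = BalancingConfig(alpha=0.0, every=1)
        out = balance_lambdas([0.1, -0.3, 0.2], [np.array([2.0, -4.0, 0.0])],
                              [1.0], cfg)
        assert out[0] == pytest.approx(0.05)

    def test_hand_smoothing(self):
        # lambda_new = 0.9 * 1 + 0.1 * 0.05 = 0.905
        cfg = BalancingConfig(alpha=0.9, every=1)
        out = balance_lambdas([0.1, -0.3, 0.2], [np.array([2.0, -4.0, 0.0])],
                              [1.0], cfg)
        assert out[0] == pytest.approx(0.905)

    def test_alpha_zero_uses_raw_ratio(self):
        cfg = BalancingConfig(alpha=0.0, every=1)
        out = balance_lambdas([4.0], [np.array([2.0])], [123.0], cfg)
        assert out[0] == pytest.approx(2.0)

    def test_zero_max_gradient_skips_update(self):
        cfg = BalancingConfig(alpha=0.5, every=1)
        out = balance_lambdas([1.0], [np.zeros(3), np.array([2.0, 0, 0])],
                              [7.0, 1.0], cfg)
        assert out[0] == 7.0  # untouched
        assert out[1] == pytest.approx(0.5 * 1.0 + 0.5 * 0.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BalancingConfig(alpha=1.0)
        with pytest.raises(ValueError):
            BalancingConfig(every=0)


class TestCurrentInterval:
    sched = PhaseSchedule(n1=10, n2=100, n3=50)

    def test_phase1_has_no_ode_interval(self):
        assert current_interval(0, self.sched, (-1, 1)) is None

    def test_phase2_growth(self):
        # local step 0: zero width at window start
        a, b = current_interval(10, self.sched, (-1, 1))
        assert (a, b) == (-1.0, -1.0)
        # halfway: half the window (window [0,2] -> [0,1])
        a, b = current_interval(60, self.sched, (0.0, 2.0))
        assert (a, b) == (0.0, 1.0)

    def test_phase3_full_window(self):
        assert current_interval(110, self.sched, (-1, 1)) == (-1.0, 1.0)

    def test_phase_bookkeeping(self):
        assert self.sched.phase_of(0) == (1, 0)
        assert self.sched.phase_of(10) == (2, 0)
        assert self.sched.phase_of(109) == (2, 99)
        assert self.sched.phase_of(110) == (3, 0)
        assert self.sched.total == 160


@pytest.fixture(scope="module")
def short_run(exp_system, exp_spec, exp_initial_obs):
    return train(
        exp_system, exp_initial_obs, exp_spec, (0.0, 2.0),
        schedule=PhaseSchedule(200, 2000, 1000, eval_every=100, patience=50),
        collocation=CollocationConfig(32),
        seed=3, eval_points=100, **DESK_NET,
    )


class TestTrainLoop:
    def test_lambda_trace_cadence(self, short_run):
        _, _, state = short_run
        steps = [row["step"] for row in state.lambda_trace]
        assert all(s % 100 == 0 for s in steps)
        assert min(steps) >= 200  # no balancing during the data-fit phase

    def test_best_eval_is_minimum_of_trace(self, short_run):
        _, _, state = short_run
        evals = [row["eval_loss"] for row in state.eval_trace]
        assert state.best_eval == pytest.approx(min(evals))

    def test_returned_weights_reproduce_best_eval(self, short_run, exp_system,
                                                  exp_spec, exp_initial_obs):
        net, models, state = short_run
        tn = exp_spec.normalize_time(exp_initial_obs.times)
        un = exp_spec.normalize_state(exp_initial_obs.values)
        ev = evaluation_loss(net, exp_system, exp_spec, tn, un, (-1.0, 1.0),
                             models, 100)
        assert ev == pytest.approx(state.best_eval, rel=1e-9)

    def test_evaluation_loss_independent_of_lambdas(self, short_run, exp_system,
                                                    exp_spec, exp_initial_obs):
        net, models, state = short_run
        tn = exp_spec.normalize_time(exp_initial_obs.times)
        un = exp_spec.normalize_state(exp_initial_obs.values)
        # evaluation is defined with all lambdas = 1 on a fixed grid:
        # recomputing after scaling state.lambdas changes nothing
        before = evaluation_loss(net, exp_system, exp_spec, tn, un, (-1, 1), models, 100)
        state.lambdas *= 100.0
        after = evaluation_loss(net, exp_system, exp_spec, tn, un, (-1, 1), models, 100)
        assert before == after

    def test_determinism_same_seed(self, exp_system, exp_spec, exp_initial_obs):
        kw = dict(schedule=PhaseSchedule(50, 300, 100, eval_every=50, patience=10),
                  collocation=CollocationConfig(16), eval_points=50, **DESK_NET)
        n1, _, s1 = train(exp_system, exp_initial_obs, exp_spec, (0, 2), seed=9, **kw)
        n2, _, s2 = train(exp_system, exp_initial_obs, exp_spec, (0, 2), seed=9, **kw)
        np.testing.assert_array_equal(n1.get_flat(), n2.get_flat())
        assert s1.best_eval == s2.best_eval

    def test_vanilla_single_phase_schedule(self, exp_system, exp_spec, exp_initial_obs):
        # (0, 0, n3) reduces to single-phase full-window training
        net, _, state = train(
            exp_system, exp_initial_obs, exp_spec, (0, 2),
            schedule=PhaseSchedule(0, 0, 500, eval_every=100, patience=None),
            balancing=BalancingConfig(enabled=False),
            collocation=CollocationConfig(16), seed=0, eval_points=50, **DESK_NET,
        )
        assert state.phase == 3
        np.testing.assert_array_equal(state.lambdas, 1.0)
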