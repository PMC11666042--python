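"""Scikit-learn style estimators wrapping the PINN training machinery.

``PINNRegressor`` handles both forward problems (all parameters known; the
data condition may be a single initial state) and inverse problems (the
system declares ``learn_*`` parameters, trained jointly with the solution
surrogate).  ``DecomposedPINNRegressor`` chains one PINN per time
subdomain for long windows.  Both follow the fit/predict contract, expose
``get_params``/``set_params`` and store fitted attributes with a trailing
underscore, so they compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import decomposition as dd
from .inverse import predict_params
from .normalization import NormalizationSpec, bounds_from_states, identity_spec
from .simulate import ObservationSet
from .systems import ODESystem, get_system
from .training import (BalancingConfig, CollocationConfig, OptimizerConfig,
                       PhaseSchedule, train)

__all__ = ["PINNRegressor", "DecomposedPINNRegressor"]


def _as_observations(t, u) -> ObservationSet:
    t = np.atleast_1d(np.asarray(t, dtype=float)).ravel()
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None] if t.size > 1 else u[None, :]
    return ObservationSet(t, u)


def _resolve_system(system) -> ODESystem:
    return get_system(system) if isinstance(system, str) else system


class PINNRegressor(BaseEstimator, RegressorMixin):
    """Physics-informed neural surrogate of an ODE solution.

    Parameters
    ----------
    system : str or ODESystem
        The governing equations; a registry name or an instance.  Systems
        with ``learn_*`` parameter entries turn fitting into a joint
        inverse problem.
    window : (float, float) or None
        Training time window in original units; defaults to the data span.
        Must be given when fitting from a single initial condition.
    normalize, balance, causal : bool
        The three training enhancements: min-max ODE normalization,
        per-equation gradient balancing, and the 3-phase causal schedule.
        With ``causal=False`` the first two phases are skipped and all
        ``phase_steps`` are spent on full-window training.
    state_bounds, param_bounds : (lower, upper) arrays or None
        Normalization bounds in original units; state bounds default to
        the min/max of the fitted data (widened 10%), which is only
        sensible when observations cover the window.
    phase_steps : (int, int, int)
        Step budgets of the data-fit, progressive and final-tuning phases.
    alpha, balance_every : float, int
        Gradient-balancing smoothing factor and update period.
    patience : int or None
        Early-stopping patience (number of evaluations without
        improvement) in the final phase; None disables early stopping.
    """

    def __init__(
        self,
        system="lorenz",
        *,
        window=None,
        normalize: bool = True,
        balance: bool = True,
        causal: bool = True,
        state_bounds=None,
        param_bounds=None,
        n_hidden_layers: int = 4,
        width: int = 100,
        param_hidden_layers: int = 4,
        param_width: int = 10,
        n_collocation: int = 128,
        phase_steps=(1000, 20000, 10000),
        alpha: float = 0.99,
        balance_every: int = 100,
        learning_rate: float = 1e-3,
        eval_every: int = 1000,
        patience: int | None = 100,
        eval_points: int = 1000,
        log_every: int = 100,
        random_state: int | None = None,
    ):
        self.system = system
        self.window = window
        self.normalize = normalize
        self.balance = balance
        self.causal = causal
        self.state_bounds = state_bounds
        self.param_bounds = param_bounds
        self.n_hidden_layers = n_hidden_layers
        self.width = width
        self.param_hidden_layers = param_hidden_layers
        self.param_width = param_width
        self.n_collocation = n_collocation
        self.phase_steps = phase_steps
        self.alpha = alpha
        self.balance_every = balance_every
        self.learning_rate = learning_rate
        self.eval_every = eval_every
        self.patience = patience
        self.eval_points = eval_points
        self.log_every = log_every
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_spec(self, system, obs, window) -> NormalizationSpec:
        if not self.normalize:
            return identity_spec(window[0], window[1], system.state_dim)
        if self.state_bounds is not None:
            lo = np.asarray(self.state_bounds[0], dtype=float)
            hi = np.asarray(self.state_bounds[1], dtype=float)
        else:
            lo, hi = bounds_from_states(obs.values, margin=0.1)
        learn = [system.param_spec[j] for j in system.learnable_indices]
        if self.param_bounds is not None:
            plo = np.asarray(self.param_bounds[0], dtype=float)
            phi = np.asarray(self.param_bounds[1], dtype=float)
        elif learn:
            missing = [p.name for p in learn if p.bounds is None]
            if missing:
                raise ValueError(f"no bounds for learnable parameter(s) {missing}")
            plo = np.array([p.bounds[0] for p in learn])
            phi = np.array([p.bounds[1] for p in learn])
        else:
            plo = phi = np.empty(0)
        return NormalizationSpec(window[0], window[1], lo, hi, plo, phi)

    def _configs(self):
        n1, n2, n3 = (int(s) for s in self.phase_steps)
        if not self.causal:
            n1, n2, n3 = 0, 0, n1 + n2 + n3
        schedule = PhaseSchedule(n1, n2, n3, eval_every=self.eval_every,
                                 patience=self.patience)
        balancing = BalancingConfig(self.alpha, self.balance_every, self.balance)
        if not self.balance:
            balancing = BalancingConfig(0.0, max(self.balance_every, 1), False)
        return schedule, balancing

    def fit(self, t, u=None):
        """Fit from observations (t_j, u_j); for forward problems the data
        may be a single initial condition."""
        obs = t if isinstance(t, ObservationSet) else _as_observations(t, u)
        system = _resolve_system(self.system)
        if self.window is not None:
            window = (float(self.window[0]), float(self.window[1]))
        else:
            if obs.n_obs < 2:
                raise ValueError("window must be given when fitting a single datum")
            window = (float(obs.times.min()), float(obs.times.max()))
        spec = self._make_spec(system, obs, window)
        schedule, balancing = self._configs()
        net, models, state = train(
            system, obs, spec, window,
            schedule=schedule,
            balancing=balancing,
            optimizer=OptimizerConfig(self.learning_rate),
            collocation=CollocationConfig(self.n_collocation),
            n_hidden_layers=self.n_hidden_layers,
            width=self.width,
            param_hidden_layers=self.param_hidden_layers,
            param_width=self.param_width,
            seed=self.random_state if self.random_state is not None else 0,
            log_every=self.log_every,
            eval_points=self.eval_points,
        )
        self.system_ = system
        self.net_ = net
        self.param_models_ = models
        self.spec_ = spec
        self.window_ = window
        self.state_ = state
        self.eval_loss_ = state.best_eval
        self.n_steps_ = state.step + 1
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")

    def predict(self, t) -> np.ndarray:
        """System states at times ``t``, in original units, shape (n, V)."""
        self._check_fitted()
        t = np.atleast_1d(np.asarray(t, dtype=float)).ravel()
        tp = self.spec_.normalize_time(t)
        return self.spec_.denormalize_state(self.net_.forward(tp[:, None]))

    def predict_params(self, t) -> np.ndarray:
        """Parameter matrix theta(t) (n, P) in original units (known +
        learned entries)."""
        self._check_fitted()
        return predict_params(self.system_, self.param_models_, t, self.spec_)


class DecomposedPINNRegressor(BaseEstimator, RegressorMixin):
    """Forward-problem PINN chained over S time subdomains.

    Fits subdomains sequentially; the first is anchored by the supplied
    data, each later one by handoff predictions on the overlap.  Bounds
    per subdomain come from ``reference`` (a ground-truth trajectory, as
    the benchmarks do), explicit ``state_bounds``, or propagation from the
    previous subdomain.
    """

    def __init__(
        self,
        system="lorenz",
        *,
        window=(0.0, 20.0),
        n_subdomains: int = 40,
        overlap: float = 0.05,
        handoff_points: int = 100,
        reference=None,
        state_bounds=None,
        n_hidden_layers: int = 4,
        width: int = 100,
        n_collocation: int = 128,
        phase_steps=(1000, 20000, 10000),
        alpha: float = 0.99,
        balance_every: int = 100,
        learning_rate: float = 1e-3,
        eval_every: int = 1000,
        patience: int | None = 100,
        eval_points: int = 1000,
        random_state: int | None = None,
    ):
        self.system = system
        self.window = window
        self.n_subdomains = n_subdomains
        self.overlap = overlap
        self.handoff_points = handoff_points
        self.reference = reference
        self.state_bounds = state_bounds
        self.n_hidden_layers = n_hidden_layers
        self.width = width
        self.n_collocation = n_collocation
        self.phase_steps = phase_steps
        self.alpha = alpha
        self.balance_every = balance_every
        self.learning_rate = learning_rate
        self.eval_every = eval_every
        self.patience = patience
        self.eval_points = eval_points
        self.random_state = random_state

    def fit(self, t, u=None):
        obs = t if isinstance(t, ObservationSet) else _as_observations(t, u)
        system = _resolve_system(self.system)
        plan = dd.partition(self.window, self.n_subdomains, self.overlap,
                            self.handoff_points)
        n1, n2, n3 = (int(s) for s in self.phase_steps)
        schedule = PhaseSchedule(n1, n2, n3, eval_every=self.eval_every,
                                 patience=self.patience)
        nets, specs, states = dd.train_decomposed(
            system, plan, obs,
            reference=self.reference,
            state_bounds=self.state_bounds,
            schedule=schedule,
            balancing=BalancingConfig(self.alpha, self.balance_every, True),
            collocation=CollocationConfig(self.n_collocation),
            optimizer=OptimizerConfig(self.learning_rate),
            n_hidden_layers=self.n_hidden_layers,
            width=self.width,
            seed=self.random_state if self.random_state is not None else 0,
            eval_points=self.eval_points,
        )
        self.system_ = system
        self.plan_ = plan
        self.nets_ = nets
        self.specs_ = specs
        self.states_ = states
        return self

    def predict(self, t) -> np.ndarray:
        if not hasattr(self, "nets_"):
            raise RuntimeError("estimator is not fitted")
        t = np.atleast_1d(np.asarray(t, dtype=float)).ravel()
        return dd.stitched_predict(self.nets_, self.specs_, self.plan_, t)
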