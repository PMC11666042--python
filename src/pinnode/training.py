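"""The optimization loop: Adam, gradient balancing, 3-phase causal schedule.

Training proceeds in three phases:

1. *data fitting* — only the data loss is minimized, giving the surrogate a
   good starting point;
2. *progressive causal training* — the full loss is minimized while the
   collocation interval grows linearly from the window start to the full
   window, so the surrogate satisfies the ODE at earlier times before later
   ones;
3. *final tuning* — full-window training with early stopping on an
   evaluation loss in which every lambda is reset to 1 and the residual is
   measured on a fixed dense grid.

Gradient balancing re-weights each equation's residual loss every N steps:
lambda_hat_i = mean|grad L_data| / max|grad L_f(i)|, smoothed by
lambda_i <- alpha lambda_i + (1 - alpha) lambda_hat_i.  The data-loss weight
stays fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import (_Packed, data_loss_grads, ode_loss, ode_loss_grads,
                     sample_collocation, total_loss)
from .nets import MLP, Adam
from .normalization import NormalizationSpec
from .inverse import make_param_models
from .simulate import ObservationSet
from .systems import ODESystem

__all__ = [
    "BalancingConfig", "PhaseSchedule", "OptimizerConfig", "CollocationConfig",
    "TrainingState", "balance_lambdas", "current_interval", "evaluation_loss",
    "train",
]


@dataclass
class BalancingConfig:
    alpha: float = 0.99
    every: int = 100
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.every < 1:
            raise ValueError("update period must be >= 1")


@dataclass
class PhaseSchedule:
    """Step budgets: n1 data-fit, n2 progressive, n3 max final-tuning steps."""

    n1: int = 1000
    n2: int = 20000
    n3: int = 10000
    eval_every: int = 1000
    patience: int | None = 100

    def __post_init__(self):
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("phase step counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3

    def phase_of(self, step: int) -> tuple[int, int]:
        """(phase number 1..3, local step within the phase)."""
        if step < self.n1:
            return 1, step
        if step < self.n1 + self.n2:
            return 2, step - self.n1
        return 3, step - self.n1 - self.n2


@dataclass
class OptimizerConfig:
    learning_rate: float = 1e-3
    decay: float | None = None  # optional exponential decay per step

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class CollocationConfig:
    n_points: int = 128

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError("need at least one collocation point")


@dataclass
class TrainingState:
    """Mutable record of a training run."""

    step: int = 0
    phase: int = 1
    lambdas: np.ndarray = field(default_factory=lambda: np.ones(1))
    loss_trace: list = field(default_factory=list)
    lambda_trace: list = field(default_factory=list)
    eval_trace: list = field(default_factory=list)
    best_eval: float = np.inf
    best_step: int = -1
    diverged: bool = False
    stopped_early: bool = False

    def loss_frame(self):
        import pandas as pd

        return pd.DataFrame(self.loss_trace)


def balance_lambdas(grad_data, grads_f, lambdas_old, cfg: BalancingConfig) -> np.ndarray:
    """One application of the balancing update.

    lambda_hat_i = mean|grad_data| / max|grads_f[i]|; a zero max gradient
    skips that equation's update (the ratio is undefined early in
    training).  Smoothing: lambda <- alpha lambda + (1-alpha) lambda_hat.
    """
    grad_data = np.abs(np.asarray(grad_data, dtype=float))
    lambdas_old = np.asarray(lambdas_old, dtype=float)
    mean_data = grad_data.mean()
    out = lambdas_old.copy()
    for i, gf in enumerate(grads_f):
        mx = np.max(np.abs(gf))
        if mx == 0.0:
            continue
        lam_hat = mean_data / mx
        out[i] = cfg.alpha * lambdas_old[i] + (1.0 - cfg.alpha) * lam_hat
    return out


def current_interval(step: int, schedule: PhaseSchedule, window) -> tuple | None:
    """Collocation interval (normalized coords) at a global step.

    Phase 1: ``None`` (no ODE loss).  Phase 2 at local step n2: the first
    n2/N2 fraction of the window.  Phase 3: the full window.
    """
    a, b = float(window[0]), float(window[1])
    phase, local = schedule.phase_of(step)
    if phase == 1:
        return None
    if phase == 2:
        frac = local / schedule.n2 if schedule.n2 else 1.0
        return (a, a + frac * (b - a))
    return (a, b)


def evaluation_loss(net, system, spec, tn_obs, un_obs, window_norm,
                    models=None, n_points: int = 1000) -> float:
    """Eq-3 loss with all lambdas = 1: data term plus the mean per-equation
    residual on a fixed dense uniform grid over the window."""
    from .losses import data_loss

    grid = np.linspace(window_norm[0], window_norm[1], n_points)
    lf = ode_loss(net, system, spec, grid, models)
    ld = data_loss(net, tn_obs, un_obs)
    return total_loss(ld, lf)


def train(
    system: ODESystem,
    obs: ObservationSet,
    spec: NormalizationSpec,
    window,
    *,
    net: MLP | None = None,
    param_models: dict | None = None,
    schedule: PhaseSchedule | None = None,
    balancing: BalancingConfig | None = None,
    optimizer: OptimizerConfig | None = None,
    collocation: CollocationConfig | None = None,
    n_hidden_layers: int = 4,
    width: int = 100,
    param_hidden_layers: int = 4,
    param_width: int = 10,
    seed: int = 0,
    log_every: int = 100,
    eval_points: int = 1000,
):
    """Run the full 3-phase loop; returns (net, param_models, TrainingState).

    The returned network carries the weights with the best evaluation loss
    seen in phase 3 (or the final weights if phase 3 never evaluated).
    """
    schedule = schedule or PhaseSchedule()
    balancing = balancing or BalancingConfig()
    optimizer = optimizer or OptimizerConfig()
    collocation = collocation or CollocationConfig()
    rng = np.random.default_rng(seed)

    if net is None:
        net = MLP.from_spec(n_hidden_layers, width, 1, system.state_dim, rng)
    if param_models is None:
        param_models = make_param_models(system, rng, param_hidden_layers, param_width)
    packed = _Packed(net, param_models)
    n_model_params = packed.n_params - net.n_params

    tn_obs = spec.normalize_time(np.asarray(obs.times, dtype=float))
    un_obs = spec.normalize_state(obs.values)
    window_norm = (float(spec.normalize_time(window[0])),
                   float(spec.normalize_time(window[1])))

    F = system.n_equations
    state = TrainingState(lambdas=np.ones(F))
    adam = Adam(optimizer.learning_rate)
    opt_state = adam.init(packed.n_params)
    params = packed.get_flat()
    best_params = None
    evals_since_best = 0

    for step in range(schedule.total):
        phase, local = schedule.phase_of(step)
        state.step, state.phase = step, phase
        interval = current_interval(step, schedule, window_norm)

        if optimizer.decay:
            adam.learning_rate = optimizer.learning_rate * np.exp(-optimizer.decay * step)

        ld, g_data = data_loss_grads(net, tn_obs, un_obs, n_extra=n_model_params)
        lf = np.zeros(F)

        if interval is None:
            grad = g_data
        else:
            a, b = interval
            if b - a <= 0:
                # zero-width growing interval at the very first phase-2 step
                b = a + 1e-9 * max(1.0, abs(window_norm[1] - window_norm[0]))
            tp = sample_collocation(collocation.n_points, (a, b), rng)
            if balancing.enabled and step % balancing.every == 0:
                lf, grads_f = ode_loss_grads(net, system, spec, tp, param_models,
                                             per_equation=True)
                state.lambdas = balance_lambdas(g_data, grads_f, state.lambdas, balancing)
                state.lambda_trace.append(
                    {"step": step, **{f"lambda_{i + 1}": v for i, v in enumerate(state.lambdas)}}
                )
                grad_ode = sum((state.lambdas[i] / F) * grads_f[i] for i in range(F))
            else:
                lf, grad_ode = ode_loss_grads(net, system, spec, tp, param_models,
                                              weights=state.lambdas / F)
            grad = g_data + grad_ode

        current_total = total_loss(ld, lf, state.lambdas if interval is not None else None)
        if not np.isfinite(current_total) or not np.all(np.isfinite(grad)):
            state.diverged = True
            break

        if step % log_every == 0:
            state.loss_trace.append({
                "step": step, "phase": phase, "L_data": ld,
                **{f"L_f_{i + 1}": lf[i] for i in range(F)},
                "total": current_total,
            })

        params = adam.update(opt_state, params, grad)
        packed.set_flat(params)

        if phase == 3 and (local + 1) % schedule.eval_every == 0:
            ev = evaluation_loss(net, system, spec, tn_obs, un_obs, window_norm,
                                 param_models, eval_points)
            state.eval_trace.append({"step": step, "eval_loss": ev})
            if ev < state.best_eval:
                state.best_eval, state.best_step = ev, step
                best_params = params.copy()
                evals_since_best = 0
            else:
                evals_since_best += 1
                if schedule.patience is not None and evals_since_best >= schedule.patience:
                    state.stopped_early = True
                    break

    if best_params is not None:
        packed.set_flat(best_params)
    else:
        # no evaluation happened (e.g. n3 < eval_every); keep last finite weights
        packed.set_flat(params)
        state.best_eval = evaluation_loss(net, system, spec, tn_obs, un_obs,
                                          window_norm, param_models, eval_points)
        state.best_step = state.step
    return net, param_models, state
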