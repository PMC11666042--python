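"""Time-domain decomposition: sequential subdomain training with overlap handoff.

The window [T0, TS] is split into S equal non-overlapping cores
[T_{s-1}, T_s]; each subdomain trains an independent PINN on its extended
domain [T_{s-1} - O, T_s + O] (clipped to the window).  The first subdomain
uses the user-supplied data condition; each later one is anchored by
*handoff data*: predictions of the previous network at evenly spaced times
on the overlap interface [T_{s-1}, T_{s-1} + O].  The stitched global
predictor answers each query from the network whose core contains it
(cores are left-closed/right-open; the last is closed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalization import NormalizationSpec, bounds_from_states
from .simulate import ObservationSet, Trajectory
from .training import (BalancingConfig, CollocationConfig, OptimizerConfig,
                       PhaseSchedule, train)

__all__ = ["DecompositionPlan", "partition", "handoff_data",
           "stitched_predict", "train_decomposed"]


@dataclass
class DecompositionPlan:
    boundaries: np.ndarray  # T0 < T1 < ... < TS
    overlap: float  # one-sided extension O
    handoff_points: int = 100

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 1 or self.boundaries.size < 2:
            raise ValueError("need at least two boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.overlap < 0:
            raise ValueError("overlap must be non-negative")
        if self.overlap >= np.min(np.diff(self.boundaries)):
            raise ValueError("overlap must be smaller than the core width")
        if self.handoff_points < 1:
            raise ValueError("need at least one handoff point")

    @property
    def n_subdomains(self) -> int:
        return self.boundaries.size - 1

    @property
    def window(self) -> tuple[float, float]:
        return float(self.boundaries[0]), float(self.boundaries[-1])

    def core(self, s: int) -> tuple[float, float]:
        """Core subdomain s (1-based), [T_{s-1}, T_s]."""
        return float(self.boundaries[s - 1]), float(self.boundaries[s])

    def extended(self, s: int) -> tuple[float, float]:
        """Extended subdomain, clipped at the window ends."""
        lo, hi = self.core(s)
        w0, w1 = self.window
        return max(lo - self.overlap, w0), min(hi + self.overlap, w1)

    def interface(self, s: int) -> tuple[float, float]:
        """Handoff interface feeding subdomain s (s >= 2): [T_{s-1}, T_{s-1}+O]."""
        if s < 2:
            raise ValueError("the first subdomain has no handoff interface")
        return float(self.boundaries[s - 1]), float(self.boundaries[s - 1] + self.overlap)


def partition(window, S: int, O: float, handoff_points: int = 100) -> DecompositionPlan:
    """Equal-width cores over the window with one-sided extension O."""
    t0, t1 = float(window[0]), float(window[1])
    if S < 1:
        raise ValueError("need at least one subdomain")
    return DecompositionPlan(np.linspace(t0, t1, S + 1), O, handoff_points)


def handoff_data(net, spec: NormalizationSpec, interface, n_points: int) -> ObservationSet:
    """Predictions of a trained subdomain net on its interface, as data.

    ``n_points`` evenly spaced times on [a, b]; values are denormalized to
    original units.
    """
    a, b = float(interface[0]), float(interface[1])
    times = np.linspace(a, b, n_points) if n_points > 1 else np.array([a])
    tp = spec.normalize_time(times)
    values = spec.denormalize_state(net.forward(tp[:, None]))
    return ObservationSet(times, values)


def stitched_predict(nets, specs, plan: DecompositionPlan, t) -> np.ndarray:
    """Evaluate the stitched predictor: each time answered by the network
    whose core contains it (left-closed/right-open; last core closed)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w0, w1 = plan.window
    if np.any(t < w0 - 1e-12) or np.any(t > w1 + 1e-12):
        raise ValueError(f"query time outside window [{w0}, {w1}]")
    idx = np.searchsorted(plan.boundaries, t, side="right") - 1
    idx = np.clip(idx, 0, plan.n_subdomains - 1)
    V = specs[0].state_lower.size
    out = np.empty((t.size, V))
    for s in np.unique(idx):
        mask = idx == s
        tp = specs[s].normalize_time(t[mask])
        out[mask] = specs[s].denormalize_state(nets[s].forward(tp[:, None]))
    return out


def train_decomposed(
    system,
    plan: DecompositionPlan,
    init_obs: ObservationSet,
    *,
    reference: Trajectory | None = None,
    state_bounds=None,
    schedule: PhaseSchedule | None = None,
    balancing: BalancingConfig | None = None,
    optimizer: OptimizerConfig | None = None,
    collocation: CollocationConfig | None = None,
    n_hidden_layers: int = 4,
    width: int = 100,
    seed: int = 0,
    eval_points: int = 1000,
    propagate_margin: float = 0.2,
):
    """Sequential subdomain training; returns (nets, specs, states).

    Per-subdomain state bounds come from, in order of precedence:
    explicit ``state_bounds`` (lower, upper arrays used for every
    subdomain), the ``reference`` trajectory's slice min/max, or — for
    subdomains after the first — the previous network's predictions over
    the new extended domain widened by ``propagate_margin`` on each side.
    """
    nets, specs, states = [], [], []
    # subdomain 1 reuses the master seed so an S=1 plan is step-identical
    # to a plain (non-decomposed) run
    seeds = [(seed + 1000003 * s) % (2 ** 31) for s in range(plan.n_subdomains)]
    obs = init_obs
    for s in range(1, plan.n_subdomains + 1):
        ext = plan.extended(s)
        if state_bounds is not None:
            lo, hi = np.asarray(state_bounds[0], float), np.asarray(state_bounds[1], float)
        elif reference is not None:
            grid = np.linspace(ext[0], ext[1], 201)
            lo, hi = bounds_from_states(reference.at(grid))
        elif s > 1:
            grid = np.linspace(ext[0], ext[1], 201)
            tp = specs[-1].normalize_time(grid)
            pred = specs[-1].denormalize_state(nets[-1].forward(tp[:, None]))
            lo, hi = bounds_from_states(pred, margin=propagate_margin)
        else:
            lo, hi = bounds_from_states(obs.values, margin=propagate_margin)
        spec = NormalizationSpec(ext[0], ext[1], lo, hi)
        net, _, st = train(
            system, obs, spec, ext,
            schedule=schedule, balancing=balancing, optimizer=optimizer,
            collocation=collocation, n_hidden_layers=n_hidden_layers,
            width=width, seed=int(seeds[s - 1]), eval_points=eval_points,
        )
        if st.diverged:
            raise RuntimeError(
                f"training diverged in subdomain {s}/{plan.n_subdomains}; "
                f"{s - 1} subdomain(s) completed"
            )
        nets.append(net)
        specs.append(spec)
        states.append(st)
        if s < plan.n_subdomains:
            obs = handoff_data(net, spec, plan.interface(s + 1), plan.handoff_points)
    return nets, specs, states
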