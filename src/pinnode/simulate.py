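"""Reference numerical integration and synthetic observation generation.

Ground truth for every experiment comes from an adaptive Runge-Kutta
(Dormand-Prince 4/5) integration at tight tolerances (1e-9); observation
sets are drawn from the resulting trajectory, optionally with Gaussian
noise (all benchmarks use noiseless data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .systems import ODESystem

__all__ = ["Trajectory", "ObservationSet", "integrate", "make_observations"]


@dataclass
class Trajectory:
    """A sampled solution: strictly increasing times and states (n_times, V)."""

    times: np.ndarray
    states: np.ndarray
    system_name: str = ""
    dense: object = None  # scipy dense-output interpolant, if kept

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing 1-D")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per time")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    def _check_range(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.times[0], self.times[-1]
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(f"requested time outside trajectory range [{lo}, {hi}]")
        return t

    def at(self, t) -> np.ndarray:
        """States at arbitrary times: dense interpolant if available, else linear."""
        t = self._check_range(t)
        if self.dense is not None:
            return np.asarray(self.dense(t)).T
        return self.interp_linear(t)

    def interp_linear(self, t) -> np.ndarray:
        """Componentwise linear interpolation; exact at sample times."""
        t = self._check_range(t)
        out = np.empty((t.size, self.state_dim))
        for k in range(self.state_dim):
            out[:, k] = np.interp(t, self.times, self.states[:, k])
        return out

    def to_csv(self, path, state_names=None) -> None:
        names = state_names or [f"state_{i + 1}" for i in range(self.state_dim)]
        df = pd.DataFrame(self.states, columns=names)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df.drop(columns="t").to_numpy())


@dataclass
class ObservationSet:
    """The data condition D_u = {(t_j, u_j)} in original units."""

    times: np.ndarray
    values: np.ndarray
    noise_sd: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != self.times.size:
            raise ValueError("values must have one row per observation time")

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def state_dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, state_names=None) -> None:
        names = state_names or [f"state_{i + 1}" for i in range(self.state_dim)]
        df = pd.DataFrame(self.values, columns=names)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df.drop(columns="t").to_numpy())


def integrate(
    system: ODESystem,
    u0,
    t_span,
    eval_times=None,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    params=None,
    keep_dense: bool = True,
) -> Trajectory:
    """Integrate a system with RK45 (Dormand-Prince) at tight tolerances.

    ``params``: optional mapping name -> model/constant for learnable
    entries; by default the ground-truth parameter formulas are used.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t0 < t1:
        raise ValueError("t_span start must be before end")
    if eval_times is None:
        eval_times = np.linspace(t0, t1, 1001)
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.min() < t0 - 1e-12 or eval_times.max() > t1 + 1e-12:
        raise ValueError("eval_times must lie within t_span")

    if params is None:
        theta_of_t = system.true_params
    else:
        from .systems import evaluate_params

        theta_of_t = lambda t: evaluate_params(
            system.param_spec, t, system.forcing, models=params
        )

    def f(t, u):
        ta = np.atleast_1d(t)
        return system.rhs(ta, u[None, :], theta_of_t(ta))[0]

    sol = solve_ivp(
        f,
        (t0, t1),
        np.asarray(u0, dtype=float),
        method="RK45",
        t_eval=eval_times,
        rtol=rtol,
        atol=atol,
        dense_output=keep_dense,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed near t={sol.t[-1] if sol.t.size else t0}: {sol.message}")
    return Trajectory(sol.t, sol.y.T, system.name, dense=sol.sol if keep_dense else None)


def make_observations(
    traj: Trajectory, times, noise_sd=0.0, seed: int | None = None
) -> ObservationSet:
    """Sample a trajectory at given times, adding seeded Gaussian noise.

    Noise defaults to zero: the benchmarks all use noiseless simulated data.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    values = traj.interp_linear(times)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (traj.state_dim,))
    if np.any(sd > 0):
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, 1.0, values.shape) * sd[None, :]
    return ObservationSet(times, values, noise_sd=sd.copy())
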