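"""Min-max normalization of time, state and parameters for PINN training.

Time is mapped affinely onto [-1, 1]; each state dimension and parameter is
mapped through its own (lower, upper) bounds.  Narrow bounds are widened
around the midpoint so every mapped width is at least 2, and the residual of
the ODE picks up a per-dimension rescale factor 2/(U-L) together with the
time chain factor (Tmax-Tmin)/2 that converts d/dt into d/dt'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "adjust_bounds",
    "NormalizationSpec",
    "bounds_from_states",
    "identity_spec",
]

#: widths below this trigger bound adjustment (the +-1 widening targets width 2)
_MIN_WIDTH = 2.0


def adjust_bounds(L: float, U: float) -> tuple[float, float]:
    """Widen narrow bounds around their midpoint.

    When U - L < 2, with M = (L + U)/2, returns (min(L, M-1), max(U, M+1));
    wide bounds pass through unchanged.
    """
    if L > U:
        raise ValueError("lower bound exceeds upper bound")
    if U - L >= _MIN_WIDTH:
        return float(L), float(U)
    M = 0.5 * (L + U)
    return float(min(L, M - 1.0)), float(max(U, M + 1.0))


def _adjust_pairs(lower, upper):
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    if lower.shape != upper.shape:
        raise ValueError("lower/upper bound arrays must have the same shape")
    out_l, out_u = np.empty_like(lower), np.empty_like(upper)
    for i, (lo, hi) in enumerate(zip(lower, upper)):
        out_l[i], out_u[i] = adjust_bounds(lo, hi)
    return out_l, out_u


@dataclass
class NormalizationSpec:
    """Time window and per-dimension state/parameter bounds, in original units.

    Bounds are adjusted on construction; all maps are affine and exactly
    invertible.  ``param_lower``/``param_upper`` may be empty for forward
    problems with fully known parameters.
    """

    t_min: float
    t_max: float
    state_lower: np.ndarray
    state_upper: np.ndarray
    param_lower: np.ndarray = field(default_factory=lambda: np.empty(0))
    param_upper: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t_min, self.t_max = float(self.t_min), float(self.t_max)
        if not self.t_max > self.t_min:
            raise ValueError("degenerate time window")
        self.state_lower, self.state_upper = _adjust_pairs(self.state_lower, self.state_upper)
        if np.asarray(self.param_lower).size:
            self.param_lower, self.param_upper = _adjust_pairs(self.param_lower, self.param_upper)
        else:
            self.param_lower = np.empty(0)
            self.param_upper = np.empty(0)

    # -- time ---------------------------------------------------------------
    def normalize_time(self, t):
        t = np.asarray(t, dtype=float)
        return 2.0 * (t - self.t_min) / (self.t_max - self.t_min) - 1.0

    def denormalize_time(self, tp):
        tp = np.asarray(tp, dtype=float)
        return (tp + 1.0) * (self.t_max - self.t_min) / 2.0 + self.t_min

    @property
    def time_half_width(self) -> float:
        """dt/dt' = (Tmax - Tmin)/2: the chain factor between d/dt and d/dt'."""
        return 0.5 * (self.t_max - self.t_min)

    # -- state --------------------------------------------------------------
    def normalize_state(self, u):
        u = np.asarray(u, dtype=float)
        return 2.0 * (u - self.state_lower) / (self.state_upper - self.state_lower) - 1.0

    def denormalize_state(self, up):
        up = np.asarray(up, dtype=float)
        return (up + 1.0) * (self.state_upper - self.state_lower) / 2.0 + self.state_lower

    def residual_scale(self, i: int | None = None):
        """2/(U_u - L_u): the per-dimension rescale applied to f inside the residual."""
        s = 2.0 / (self.state_upper - self.state_lower)
        return s if i is None else float(s[i])

    # -- parameters ----------------------------------------------------------
    def normalize_params(self, theta):
        theta = np.asarray(theta, dtype=float)
        return 2.0 * (theta - self.param_lower) / (self.param_upper - self.param_lower) - 1.0

    def denormalize_params(self, thp):
        thp = np.asarray(thp, dtype=float)
        return (thp + 1.0) * (self.param_upper - self.param_lower) / 2.0 + self.param_lower

    def to_dict(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "state_lower": self.state_lower.tolist(),
            "state_upper": self.state_upper.tolist(),
            "param_lower": self.param_lower.tolist(),
            "param_upper": self.param_upper.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(
            d["t_min"], d["t_max"],
            np.asarray(d["state_lower"]), np.asarray(d["state_upper"]),
            np.asarray(d.get("param_lower", [])), np.asarray(d.get("param_upper", [])),
        )


def bounds_from_states(states: np.ndarray, margin: float = 0.0):
    """Per-dimension (min, max) of an array of states, optionally widened
    by ``margin`` times the range on each side."""
    states = np.asarray(states, dtype=float)
    lo = states.min(axis=0)
    hi = states.max(axis=0)
    if margin:
        span = hi - lo
        lo = lo - margin * span
        hi = hi + margin * span
    return lo, hi


def identity_spec(
    t_min: float, t_max: float, state_dim: int, identity_time: bool = True
) -> NormalizationSpec:
    """A spec whose state (and optionally time) map is the identity.

    Used by the un-normalized ablation variant: states, parameters and the
    residual keep their original scales.  With ``identity_time`` the time
    map is also the identity (internal window (-1, 1)); training then
    samples collocation points over the original window directly.
    """
    if identity_time:
        return NormalizationSpec(-1.0, 1.0, -np.ones(state_dim), np.ones(state_dim))
    return NormalizationSpec(t_min, t_max, -np.ones(state_dim), np.ones(state_dim))
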