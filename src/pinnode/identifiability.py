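"""Time-pointwise parameter identifiability via reduced row-echelon analysis.

At a fixed time t the ODE system is linear in any parameter that enters
each equation affinely (true of all the mosquito model's development,
mortality and transition rates).  Writing A(t) theta_unknown = b(t) with
b = du/dt minus the known-parameter terms, a parameter is *unidentifiable*
at t exactly when its column is free (non-pivot) in the reduced
row-echelon form of A(t).  Entries are rounded to a fixed decimal
precision before the exact rational RREF, mirroring the numerical
precision a trained surrogate can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy

from .simulate import Trajectory
from .systems import ODESystem

__all__ = ["linearize_in_params", "rref_analysis", "profile_over_time",
           "IdentifiabilityProfile"]


def _theta_with(system: ODESystem, t: np.ndarray, unknown_idx, values) -> np.ndarray:
    theta = system.true_params(t)
    for j, v in zip(unknown_idx, values):
        theta[:, j] = v
    return theta


def linearize_in_params(system: ODESystem, t: float, u, dudt, unknown):
    """Coefficients (A, b) of the linear system A theta_unknown = b at time t.

    Columns are extracted by probing: evaluate the rhs with one unknown set
    to 1 and the rest to 0, minus the all-zero evaluation.  A second probe
    at 2 checks that each unknown really enters affinely.
    """
    t = np.atleast_1d(float(t))
    u = np.asarray(u, dtype=float).reshape(1, system.state_dim)
    dudt = np.asarray(dudt, dtype=float).reshape(system.state_dim)
    names = system.param_names
    unknown_idx = [names.index(p) for p in unknown]
    P = len(unknown_idx)

    zeros = np.zeros(P)
    f0 = system.rhs(t, u, _theta_with(system, t, unknown_idx, zeros))[0]
    A = np.empty((system.state_dim, P))
    for k in range(P):
        probe1 = zeros.copy(); probe1[k] = 1.0
        probe2 = zeros.copy(); probe2[k] = 2.0
        f1 = system.rhs(t, u, _theta_with(system, t, unknown_idx, probe1))[0]
        f2 = system.rhs(t, u, _theta_with(system, t, unknown_idx, probe2))[0]
        col = f1 - f0
        scale = 1.0 + np.abs(f0) + np.abs(f1)
        if not np.allclose(f2 - f0, 2.0 * col, atol=1e-8 * np.max(scale)):
            raise ValueError(
                f"parameter {unknown[k]!r} does not enter the system affinely at t={t[0]}"
            )
        A[:, k] = col
    b = dudt - f0
    return A, b


def rref_analysis(A, precision_digits: int = 6):
    """(rank, pivot columns, free columns) of the rounded coefficient matrix.

    Entries are rounded to ``precision_digits`` decimals, converted to
    exact rationals and reduced symbolically, so the rank decision carries
    no floating-point ambiguity beyond the stated rounding.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    q = 10 ** precision_digits
    M = sympy.Matrix(A.shape[0], A.shape[1],
                     lambda i, j: sympy.Rational(int(round(A[i, j] * q)), q))
    _, pivots = M.rref()
    pivots = tuple(int(p) for p in pivots)
    free = tuple(j for j in range(A.shape[1]) if j not in pivots)
    return len(pivots), pivots, free


@dataclass
class IdentifiabilityProfile:
    """Per-time identifiability flags for a set of unknown parameters."""

    times: np.ndarray
    unknown: list
    identifiable: np.ndarray  # (n_times, P) boolean
    rank: np.ndarray  # (n_times,)
    precision_digits: int = 6

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.identifiable, columns=self.unknown)
        df.insert(0, "t", self.times)
        df["rank"] = self.rank
        return df

    def free_fraction(self) -> pd.Series:
        """Fraction of analyzed times at which each parameter is free."""
        return pd.Series(1.0 - self.identifiable.mean(axis=0), index=self.unknown)

    def free_intervals(self, name: str) -> list[tuple[float, float]]:
        """Maximal contiguous time intervals where a parameter is free."""
        j = self.unknown.index(name)
        free = ~self.identifiable[:, j]
        out, start = [], None
        for t, fl in zip(self.times, free):
            if fl and start is None:
                start = t
            elif not fl and start is not None:
                out.append((start, prev))
                start = None
            prev = t
        if start is not None:
            out.append((start, self.times[-1]))
        return out


def profile_over_time(
    system: ODESystem,
    trajectory: Trajectory,
    unknown,
    times,
    precision_digits: int = 6,
) -> IdentifiabilityProfile:
    """RREF identifiability analysis performed separately at each time.

    Derivatives du/dt are taken from the rhs evaluated on the reference
    trajectory (the noise-free setting); the free-parameter count at each
    time equals P_unknown minus the matrix rank there.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    unknown = list(unknown)
    P = len(unknown)
    states = trajectory.at(times)
    ident = np.ones((times.size, P), dtype=bool)
    rank = np.full(times.size, P, dtype=int)
    for i, t in enumerate(times):
        u = states[i]
        dudt = system(t, u)
        A, _ = linearize_in_params(system, t, u, dudt, unknown)
        r, _, free = rref_analysis(A, precision_digits)
        rank[i] = r
        for j in free:
            ident[i, j] = False
    return IdentifiabilityProfile(times, unknown, ident, rank, precision_digits)
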