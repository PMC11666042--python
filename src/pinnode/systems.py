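"""ODE system definitions.

A system is a set of first-order ODEs du/dt = f(t, u, theta) over a
V-dimensional state, with an ordered parameter specification.  Two systems
ship with the package: the Lorenz system (the classic chaotic benchmark)
and a 10-stage compartmental model of mosquito population dynamics whose
rates may depend on a seasonal temperature forcing.

All right-hand sides are vectorized: ``t`` has shape ``(n,)``, ``u`` shape
``(n, V)`` and ``theta`` shape ``(n, P)``; the result has shape ``(n, V)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParamSpec",
    "ODESystem",
    "lorenz_system",
    "lorenz_rhs",
    "lorenz_timevarying_params",
    "lorenz_inverse_system",
    "seasonal_temperature",
    "default_mosquito_rates",
    "mosquito_system",
    "mosquito_rhs",
    "evaluate_params",
    "get_system",
    "register_system",
]

KNOWN_CONSTANT = "known_constant"
KNOWN_FUNCTION = "known_function_of_time"
LEARN_CONSTANT = "learn_constant"
LEARN_FUNCTION = "learn_function_of_time"

_KINDS = {KNOWN_CONSTANT, KNOWN_FUNCTION, LEARN_CONSTANT, LEARN_FUNCTION}


@dataclass
class ParamSpec:
    """Specification of one system parameter.

    ``value`` holds the true constant or the true time/temperature formula;
    it is used only by the data generator and for scoring recovered
    parameters — the training loop never reads it for ``learn_*`` kinds.
    ``of`` says whether a callable value takes time ``t`` or the forcing
    output (temperature) as its argument.
    """

    name: str
    kind: str = KNOWN_CONSTANT
    value: float | Callable[[np.ndarray], np.ndarray] | None = None
    bounds: tuple[float, float] | None = None
    of: str = "t"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.of not in ("t", "temperature"):
            raise ValueError(f"unknown argument tag {self.of!r}")
        if self.bounds is not None and self.bounds[0] > self.bounds[1]:
            raise ValueError(f"bounds for {self.name!r} are reversed")

    @property
    def learnable(self) -> bool:
        return self.kind in (LEARN_CONSTANT, LEARN_FUNCTION)

    def true_values(self, t: np.ndarray, forcing=None) -> np.ndarray:
        """Evaluate the ground-truth value at times ``t`` (original units)."""
        t = np.asarray(t, dtype=float)
        if callable(self.value):
            arg = t if self.of == "t" else _apply_forcing(forcing, t, self.name)
            return np.broadcast_to(np.asarray(self.value(arg), dtype=float), t.shape).copy()
        if self.value is None:
            raise ValueError(f"parameter {self.name!r} has no true value")
        return np.full_like(t, float(self.value))


def _apply_forcing(forcing, t, name):
    if forcing is None:
        raise ValueError(
            f"parameter {name!r} is a function of temperature but no forcing was given"
        )
    return np.asarray(forcing(t), dtype=float)


@dataclass
class ODESystem:
    """A first-order ODE system du/dt = f(t, u, theta).

    ``rhs(t, u, theta)`` must accept arrays shaped ``(n,)``, ``(n, V)``,
    ``(n, P)`` and return ``(n, V)``.  ``jac_state`` (optional) returns the
    state Jacobian with shape ``(n, V, V)``; when absent, callers fall back
    to finite differences.  ``forcing`` maps time to the environmental
    driver (temperature for the mosquito model) and is applied when
    evaluating temperature-dependent parameters.
    """

    name: str
    state_dim: int
    rhs: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    param_spec: list[ParamSpec] = field(default_factory=list)
    state_names: Sequence[str] | None = None
    jac_state: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None
    forcing: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.state_dim < 1:
            raise ValueError("state_dim must be positive")
        if self.state_names is None:
            self.state_names = [f"u{i + 1}" for i in range(self.state_dim)]
        if len(self.state_names) != self.state_dim:
            raise ValueError("state_names length must equal state_dim")

    @property
    def n_equations(self) -> int:
        return self.state_dim

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.param_spec]

    @property
    def learnable_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.param_spec) if p.learnable]

    def true_params(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth parameter matrix theta(t), shape ``(n, P)``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [p.true_values(t, self.forcing) for p in self.param_spec]
        if not cols:
            return np.empty((t.size, 0))
        return np.stack(cols, axis=1)

    def __call__(self, t, u, theta=None):
        """Evaluate the rhs at a single time point (convenience form)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        u = np.asarray(u, dtype=float).reshape(1, self.state_dim)
        if not np.all(np.isfinite(u)):
            raise ValueError("state vector contains non-finite values")
        th = self.true_params(t) if theta is None else np.asarray(theta, float).reshape(1, -1)
        out = self.rhs(t, u, th)[0]
        if not np.all(np.isfinite(out)):
            raise ValueError("rhs returned non-finite values")
        return out

    def jac_state_fd(self, t, u, theta, h: float = 1e-6) -> np.ndarray:
        """Central finite-difference state Jacobian, shape ``(n, V, V)``."""
        n, V = u.shape
        J = np.empty((n, V, V))
        for k in range(V):
            step = h * (1.0 + np.abs(u[:, k]))
            up, um = u.copy(), u.copy()
            up[:, k] += step
            um[:, k] -= step
            J[:, :, k] = (self.rhs(t, up, theta) - self.rhs(t, um, theta)) / (2 * step[:, None])
        return J

    def state_jacobian(self, t, u, theta) -> np.ndarray:
        if self.jac_state is not None:
            return self.jac_state(t, u, theta)
        return self.jac_state_fd(t, u, theta)


# ---------------------------------------------------------------------------
# Lorenz system
# ---------------------------------------------------------------------------

def lorenz_rhs(t, u, theta):
    """Lorenz equations: dx/dt = sigma(y-x), dy/dt = x(rho-z)-y, dz/dt = xy-beta z."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("state vector contains non-finite values")
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    sigma, rho, beta = theta[:, 0], theta[:, 1], theta[:, 2]
    return np.stack(
        [sigma * (y - x), x * (rho - z) - y, x * y - beta * z], axis=1
    )


def _lorenz_jac(t, u, theta):
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    sigma, rho, beta = theta[:, 0], theta[:, 1], theta[:, 2]
    n = u.shape[0]
    J = np.zeros((n, 3, 3))
    J[:, 0, 0] = -sigma
    J[:, 0, 1] = sigma
    J[:, 1, 0] = rho - z
    J[:, 1, 1] = -1.0
    J[:, 1, 2] = -x
    J[:, 2, 0] = y
    J[:, 2, 1] = x
    J[:, 2, 2] = -beta
    return J


def lorenz_system(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0) -> ODESystem:
    """The constant-parameter Lorenz benchmark (sigma=10, rho=28, beta=8/3)."""
    spec = [
        ParamSpec("sigma", KNOWN_CONSTANT, sigma, bounds=(0.0, 2 * sigma)),
        ParamSpec("rho", KNOWN_CONSTANT, rho, bounds=(0.0, 2 * rho)),
        ParamSpec("beta", KNOWN_CONSTANT, beta, bounds=(0.0, 2 * beta)),
    ]
    return ODESystem(
        name="lorenz",
        state_dim=3,
        rhs=lorenz_rhs,
        param_spec=spec,
        state_names=["x", "y", "z"],
        jac_state=_lorenz_jac,
    )


def lorenz_timevarying_params(t):
    """Ground-truth parameters of the time-varying inverse benchmark.

    sigma(t) = (10/2) sin(2 pi t) + 10, rho(t) = (28/5) sin(2 pi t + pi/2) + 28,
    beta = 8/3; both sigma and rho have period 1 in t.
    """
    t = np.asarray(t, dtype=float)
    sigma = (10.0 / 2.0) * np.sin(2 * np.pi * t) + 10.0
    rho = (28.0 / 5.0) * np.sin(2 * np.pi * t + np.pi / 2.0) + 28.0
    beta = np.full_like(t, 8.0 / 3.0)
    return sigma, rho, beta


def lorenz_inverse_system() -> ODESystem:
    """Lorenz with time-varying sigma, rho, beta, all to be learnt from data."""
    spec = [
        ParamSpec(
            "sigma", LEARN_FUNCTION,
            lambda t: (10.0 / 2.0) * np.sin(2 * np.pi * t) + 10.0,
            bounds=(4.0, 16.5),
        ),
        ParamSpec(
            "rho", LEARN_FUNCTION,
            lambda t: (28.0 / 5.0) * np.sin(2 * np.pi * t + np.pi / 2.0) + 28.0,
            bounds=(20.0, 37.0),
        ),
        ParamSpec("beta", LEARN_CONSTANT, 8.0 / 3.0, bounds=(0.0, 6.0)),
    ]
    return ODESystem(
        name="lorenz_inverse",
        state_dim=3,
        rhs=lorenz_rhs,
        param_spec=spec,
        state_names=["x", "y", "z"],
        jac_state=_lorenz_jac,
    )


# ---------------------------------------------------------------------------
# Mosquito population dynamics (10 developmental stages)
# ---------------------------------------------------------------------------

MOSQUITO_STAGES = ["E", "L", "P", "Aem", "Ab1", "Ag1", "Ao1", "Ab2", "Ag2", "Ao2"]

#: parameter order used by :func:`mosquito_rhs`
MOSQUITO_PARAMS = [
    "gamma_Ao", "gamma_Aem", "gamma_Ab", "beta1", "beta2",
    "mu_E", "mu_r", "mu_em",
    "f_E", "f_L", "f_P", "f_Ag",
    "m_L", "m_P", "m_A",
    "kappa_L", "kappa_P", "sigma_em",
]


def seasonal_temperature(t):
    """Benchmark sinusoidal forcing tau(t) = 10 sin(2 pi t / 365) + 10 (deg C, t in days)."""
    return 10.0 * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / 365.0) + 10.0


def _logistic(tau, peak, center, slope=0.3):
    return peak / (1.0 + np.exp(-slope * (np.asarray(tau, dtype=float) - center)))


def default_mosquito_rates() -> dict:
    """Registry of rate constants/functions for the mosquito model.

    The temperature-dependent forms below are documented placeholders with
    Culex-like magnitudes: logistic development rates that shut down in the
    cold, and mortalities that rise exponentially as temperature drops.
    Any entry may be overridden with a constant or a callable of
    temperature.
    """
    return {
        # adult stage-transition rates (1/day)
        "gamma_Ao": 2.0,
        "gamma_Aem": 0.4,
        "gamma_Ab": 0.2,
        # egg laying (eggs/day per ovipositing adult)
        "beta1": 141.0,
        "beta2": 80.0,
        # mortality / risk rates (1/day)
        "mu_E": 0.1,
        "mu_r": 0.08,
        "mu_em": 0.1,
        # temperature-dependent development rates (1/day)
        "f_E": lambda tau: _logistic(tau, 0.50, 10.0),
        "f_L": lambda tau: _logistic(tau, 0.20, 12.0),
        "f_P": lambda tau: _logistic(tau, 0.30, 12.0),
        "f_Ag": lambda tau: _logistic(tau, 0.20, 10.0),
        # temperature-dependent mortalities (1/day)
        "m_L": lambda tau: 0.02 + 0.30 * np.exp(-np.asarray(tau, float) / 5.0),
        "m_P": lambda tau: 0.02 + 0.25 * np.exp(-np.asarray(tau, float) / 5.0),
        "m_A": lambda tau: 0.03 + 0.10 * np.exp(-np.asarray(tau, float) / 6.0),
        # carrying capacities (organisms) and emergence coefficient
        "kappa_L": 1e8,
        "kappa_P": 1e7,
        "sigma_em": 0.5,
    }


def mosquito_rhs(t, u, theta, exponent_form: str = "density"):
    """Stage derivatives of the 10-compartment mosquito model.

    State order: E, L, P, Aem, Ab1, Ag1, Ao1, Ab2, Ag2, Ao2.  Larval
    mortality is density dependent, m_L (1 + L/kappa_L); adult emergence is
    damped by sigma_em exp(-mu_em (1 + P/kappa_P)) (``exponent_form="density"``)
    or by the constant-exponent variant exp(-mu_em (1 + 1/kappa_P))
    (``exponent_form="constant"``).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("state vector contains non-finite values")
    (gAo, gAem, gAb, b1, b2, muE, mur, muem,
     fE, fL, fP, fAg, mL, mP, mA, kL, kP, sem) = (theta[:, i] for i in range(18))
    if np.any(kL <= 0) or np.any(kP <= 0):
        raise ValueError("carrying capacities kappa_L, kappa_P must be positive")
    E, L, P, Aem, Ab1, Ag1, Ao1, Ab2, Ag2, Ao2 = (u[:, i] for i in range(10))
    if exponent_form == "density":
        emer = fP * sem * np.exp(-muem * (1.0 + P / kP))
    elif exponent_form == "constant":
        emer = fP * sem * np.exp(-muem * (1.0 + 1.0 / kP))
    else:
        raise ValueError(f"unknown exponent_form {exponent_form!r}")
    out = np.empty_like(u)
    out[:, 0] = gAo * (b1 * Ao1 + b2 * Ao2) - (muE + fE) * E
    out[:, 1] = fE * E - (mL * (1.0 + L / kL) + fL) * L
    out[:, 2] = fL * L - (mP + fP) * P
    out[:, 3] = emer * P - (mA + gAem) * Aem
    out[:, 4] = gAem * Aem - (mA + mur + gAb) * Ab1
    out[:, 5] = gAb * Ab1 - (mA + fAg) * Ag1
    out[:, 6] = fAg * Ag1 - (mA + mur + gAo) * Ao1
    out[:, 7] = gAo * (Ao1 + Ao2) - (mA + mur + gAb) * Ab2
    out[:, 8] = gAb * Ab2 - (mA + fAg) * Ag2
    out[:, 9] = fAg * Ag2 - (mA + mur + gAo) * Ao2
    return out


def _mosquito_jac(t, u, theta, exponent_form: str = "density"):
    (gAo, gAem, gAb, b1, b2, muE, mur, muem,
     fE, fL, fP, fAg, mL, mP, mA, kL, kP, sem) = (theta[:, i] for i in range(18))
    E, L, P = u[:, 0], u[:, 1], u[:, 2]
    n = u.shape[0]
    J = np.zeros((n, 10, 10))
    J[:, 0, 0] = -(muE + fE)
    J[:, 0, 6] = gAo * b1
    J[:, 0, 9] = gAo * b2
    J[:, 1, 0] = fE
    J[:, 1, 1] = -(mL * (1.0 + 2.0 * L / kL) + fL)
    J[:, 2, 1] = fL
    J[:, 2, 2] = -(mP + fP)
    if exponent_form == "density":
        ex = np.exp(-muem * (1.0 + P / kP))
        J[:, 3, 2] = fP * sem * ex * (1.0 - muem * P / kP)
    else:
        J[:, 3, 2] = fP * sem * np.exp(-muem * (1.0 + 1.0 / kP))
    J[:, 3, 3] = -(mA + gAem)
    J[:, 4, 3] = gAem
    J[:, 4, 4] = -(mA + mur + gAb)
    J[:, 5, 4] = gAb
    J[:, 5, 5] = -(mA + fAg)
    J[:, 6, 5] = fAg
    J[:, 6, 6] = -(mA + mur + gAo)
    J[:, 7, 6] = gAo
    J[:, 7, 9] = gAo
    J[:, 7, 7] = -(mA + mur + gAb)
    J[:, 8, 7] = gAb
    J[:, 8, 8] = -(mA + fAg)
    J[:, 9, 8] = fAg
    J[:, 9, 9] = -(mA + mur + gAo)
    return J


_MOSQUITO_LEARNABLE_DEFAULT = (
    "gamma_Aem", "gamma_Ab", "gamma_Ao",
    "f_E", "f_P", "f_L", "f_Ag", "m_L", "m_P", "m_A",
)

_MOSQUITO_CONSTANT_LEARNABLES = ("gamma_Aem", "gamma_Ab", "gamma_Ao")


def mosquito_system(
    rates: dict | None = None,
    exponent_form: str = "density",
    forcing: Callable = seasonal_temperature,
    learnable: Sequence[str] = (),
) -> ODESystem:
    """Build the 10-stage mosquito system from a rate registry.

    ``learnable`` names parameters to mark as unknown (for inverse
    problems): the three adult transition rates become learnable constants,
    everything else a learnable function of time.  Bounds for learnable
    rates default to (0, 2 x max true value over a seasonal cycle).
    """
    registry = default_mosquito_rates()
    if rates:
        unknown = set(rates) - set(registry)
        if unknown:
            raise ValueError(f"unknown mosquito rate(s): {sorted(unknown)}")
        registry.update(rates)
    bad = set(learnable) - set(MOSQUITO_PARAMS)
    if bad:
        raise ValueError(f"unknown learnable parameter(s): {sorted(bad)}")

    tau_grid = np.linspace(0.0, 365.0, 200)
    spec = []
    for name in MOSQUITO_PARAMS:
        val = registry[name]
        of = "temperature" if callable(val) else "t"
        if name in learnable:
            if callable(val):
                top = float(np.max(val(seasonal_temperature(tau_grid))))
            else:
                top = float(val)
            kind = LEARN_CONSTANT if name in _MOSQUITO_CONSTANT_LEARNABLES else LEARN_FUNCTION
            spec.append(ParamSpec(name, kind, val, bounds=(0.0, 2.0 * max(top, 1e-6)), of=of))
        else:
            kind = KNOWN_FUNCTION if callable(val) else KNOWN_CONSTANT
            spec.append(ParamSpec(name, kind, val, of=of))

    return ODESystem(
        name="mosquito",
        state_dim=10,
        rhs=lambda t, u, th: mosquito_rhs(t, u, th, exponent_form),
        param_spec=spec,
        state_names=list(MOSQUITO_STAGES),
        jac_state=lambda t, u, th: _mosquito_jac(t, u, th, exponent_form),
        forcing=forcing,
    )


# ---------------------------------------------------------------------------
# Parameter evaluation & registry
# ---------------------------------------------------------------------------

def evaluate_params(spec: Sequence[ParamSpec], t, forcing=None, models=None):
    """Evaluate an ordered parameter specification at times ``t``.

    Known entries come from their constants/formulas; ``learn_*`` entries
    require a trained model in ``models`` (a mapping name -> object with a
    ``values_at(t_norm)`` method is resolved by the inverse module; here a
    plain callable of t or a constant is also accepted).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    cols = []
    for p in spec:
        if p.learnable:
            if models is None or p.name not in models:
                raise ValueError(f"learnable parameter {p.name!r} has no bound model")
            m = models[p.name]
            vals = m(t) if callable(m) else np.full_like(t, float(m))
            cols.append(np.asarray(vals, dtype=float))
        else:
            cols.append(p.true_values(t, forcing))
    if not cols:
        return np.empty((t.size, 0))
    return np.stack(cols, axis=1)


_REGISTRY: dict[str, Callable[[], ODESystem]] = {
    "lorenz": lorenz_system,
    "lorenz_inverse": lorenz_inverse_system,
    "mosquito": mosquito_system,
}


def register_system(name: str, factory: Callable[[], ODESystem]) -> None:
    """Register a custom system factory addressable by name."""
    _REGISTRY[name] = factory


def get_system(name: str, **kwargs) -> ODESystem:
    """Instantiate a registered system by name."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown system {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**kwargs)
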