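"""Trainable parameter models for inverse problems.

Unknown ODE parameters live in normalized space (through their
ParamSpec bounds), as either a single trainable scalar (parameters that
are constant over time) or a small MLP of normalized time (parameters
that vary).  Gradient balancing then sees O(1) scales for parameters just
as it does for states.
"""

from __future__ import annotations

import numpy as np

from .nets import MLP
from .normalization import NormalizationSpec
from .systems import LEARN_CONSTANT, ODESystem

__all__ = ["ConstantParam", "NetworkParam", "make_param_models", "predict_params",
           "recover_parameters"]


class ConstantParam:
    """A single trainable scalar in normalized parameter space."""

    kind = "constant"

    def __init__(self, init: float = 0.0):
        self.value = float(init)

    @property
    def n_params(self) -> int:
        return 1

    def get_flat(self) -> np.ndarray:
        return np.array([self.value])

    def set_flat(self, flat: np.ndarray) -> None:
        self.value = float(flat[0])

    def forward(self, tp: np.ndarray, cache: bool = False):
        out = np.full(np.asarray(tp).shape[0] if np.ndim(tp) else 1, self.value)
        return (out, None) if cache else out

    def backward(self, cache, g: np.ndarray) -> np.ndarray:
        # gradient flows through a single scalar, shared by every time point
        return np.array([float(np.sum(g))])

    def copy(self) -> "ConstantParam":
        return ConstantParam(self.value)


class NetworkParam:
    """A small MLP t' -> normalized parameter value (default 4 x 10, GELU)."""

    kind = "network"

    def __init__(self, n_hidden_layers: int = 4, width: int = 10, rng=None, net: MLP | None = None):
        self.net = net if net is not None else MLP.from_spec(n_hidden_layers, width, 1, 1, rng)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def get_flat(self) -> np.ndarray:
        return self.net.get_flat()

    def set_flat(self, flat: np.ndarray) -> None:
        self.net.set_flat(flat)

    def forward(self, tp: np.ndarray, cache: bool = False):
        tp = np.atleast_1d(np.asarray(tp, dtype=float))
        if cache:
            y, c = self.net.forward(tp[:, None], cache=True)
            return y[:, 0], c
        return self.net.forward(tp[:, None])[:, 0]

    def backward(self, cache, g: np.ndarray) -> np.ndarray:
        grads = self.net.backward(cache, np.asarray(g, dtype=float)[:, None])
        return MLP.flatten_grads(grads)

    def copy(self) -> "NetworkParam":
        return NetworkParam(net=self.net.copy())


def make_param_models(system: ODESystem, rng, n_hidden_layers: int = 4, width: int = 10) -> dict:
    """One model per ``learn_*`` entry of the system's parameter spec."""
    models = {}
    for p in system.param_spec:
        if not p.learnable:
            continue
        if p.kind == LEARN_CONSTANT:
            models[p.name] = ConstantParam(0.0)
        else:
            models[p.name] = NetworkParam(n_hidden_layers, width, rng)
    return models


def predict_params(
    system: ODESystem,
    models: dict,
    t,
    spec: NormalizationSpec,
) -> np.ndarray:
    """Parameter matrix (n_times, P) in original units.

    Known parameters come from their formulas; learned ones from their
    models, denormalized through the spec's parameter bounds (ordered as
    the system's learnable entries).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tp = spec.normalize_time(t)
    P = len(system.param_spec)
    theta = np.empty((t.size, P))
    li = 0
    for j, p in enumerate(system.param_spec):
        if p.learnable:
            if p.name not in models:
                raise ValueError(f"learnable parameter {p.name!r} has no model")
            raw = models[p.name].forward(tp)
            lo, hi = spec.param_lower[li], spec.param_upper[li]
            theta[:, j] = (raw + 1.0) * (hi - lo) / 2.0 + lo
            li += 1
        else:
            theta[:, j] = p.true_values(t, system.forcing)
    return theta


def recover_parameters(system, obs, spec, window, *, seed=0, **train_kwargs):
    """Joint training of the solution surrogate and the parameter models.

    A thin functional wrapper over :func:`pinnode.training.train` for
    systems with learnable parameters; returns the trained solution net,
    the parameter models and the training state.
    """
    from .training import train

    return train(system, obs, spec, window, seed=seed, **train_kwargs)
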