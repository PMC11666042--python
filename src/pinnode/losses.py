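"""Loss terms of the PINN objective in normalized coordinates.

The total loss is ``L = L_data + (1/F) sum_i lambda_i L_f(i)``: a mean
squared data misfit plus one mean squared ODE residual per equation.  The
residual of equation i at a normalized collocation time t' is

    dU_i/dt'  -  (2 / (Uu_i - Lu_i)) * ((Tmax - Tmin) / 2) * f_i(t, u, theta)

where the first factor rescales the equation to the normalized state and
the second is the chain factor converting d/dt to d/dt' (equal to 1 when
the window already has width 2, as in the short Lorenz benchmarks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import MLP
from .normalization import NormalizationSpec
from .systems import ODESystem

__all__ = ["LossState", "sample_collocation", "data_loss", "ode_loss",
           "data_loss_grads", "ode_loss_grads", "total_loss"]


@dataclass
class LossState:
    """One evaluation of the composite objective."""

    data: float
    ode: np.ndarray  # per-equation L_f(i)
    lambdas: np.ndarray

    @property
    def total(self) -> float:
        F = self.ode.size
        return float(self.data + (self.lambdas * self.ode).sum() / F) if F else float(self.data)


def total_loss(data: float, ode: np.ndarray, lambdas=None) -> float:
    ode = np.asarray(ode, dtype=float)
    if lambdas is None:
        lambdas = np.ones_like(ode)
    return LossState(data, ode, np.asarray(lambdas, dtype=float)).total


def sample_collocation(n: int, interval, rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. uniform points on the open interval (a, b)."""
    a, b = float(interval[0]), float(interval[1])
    if a >= b:
        raise ValueError("collocation interval must have a < b")
    if n < 1:
        raise ValueError("need at least one collocation point")
    return rng.uniform(a, b, size=int(n))


# ---------------------------------------------------------------------------
# forward evaluations
# ---------------------------------------------------------------------------

def _learnable_theta(system, models, spec, tp, cache=False):
    """Columns of theta for learnable parameters (original units) + caches."""
    caches = {}
    cols = {}
    for li, j in enumerate(system.learnable_indices):
        name = system.param_spec[j].name
        model = models[name]
        if cache:
            raw, c = model.forward(tp, cache=True)
            caches[name] = (raw, c)
        else:
            raw = model.forward(tp)
        lo, hi = spec.param_lower[li], spec.param_upper[li]
        cols[j] = (raw + 1.0) * (hi - lo) / 2.0 + lo
    return cols, caches


def _theta_matrix(system, models, spec, tp, t, cache=False):
    P = len(system.param_spec)
    theta = np.empty((t.size, P))
    learn_cols, caches = _learnable_theta(system, models or {}, spec, tp, cache)
    for j, p in enumerate(system.param_spec):
        if p.learnable:
            theta[:, j] = learn_cols[j]
        else:
            theta[:, j] = p.true_values(t, system.forcing)
    return theta, caches


def data_loss(net: MLP, tn_obs, un_obs) -> float:
    """Mean squared error in normalized units, averaged over records and dims."""
    tn_obs = np.atleast_1d(np.asarray(tn_obs, dtype=float))
    if tn_obs.size == 0:
        raise ValueError("empty observation set")
    U = net.forward(tn_obs[:, None])
    return float(np.mean((U - un_obs) ** 2))


def ode_loss(net, system, spec, tp, models=None) -> np.ndarray:
    """Per-equation mean squared normalized residual at collocation times."""
    lf, *_ = _ode_forward(net, system, spec, tp, models, cache=False)
    return lf


def _ode_forward(net, system, spec, tp, models, cache):
    tp = np.atleast_1d(np.asarray(tp, dtype=float))
    t = spec.denormalize_time(tp)
    if cache:
        U, Ud, net_cache = net.forward_with_tangent(tp[:, None], cache=True)
    else:
        U, Ud = net.forward_with_tangent(tp[:, None])
        net_cache = None
    u = spec.denormalize_state(U)
    theta, model_caches = _theta_matrix(system, models, spec, tp, t, cache)
    f = system.rhs(t, u, theta)
    scale = spec.residual_scale() * spec.time_half_width
    r = Ud - scale[None, :] * f
    lf = np.mean(r * r, axis=0)
    return lf, r, (t, tp, U, Ud, u, theta, f, scale, net_cache, model_caches)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

@dataclass
class _Packed:
    """Bookkeeping for the global flat parameter vector (net + param models)."""

    net: MLP
    models: dict

    @property
    def model_names(self):
        return sorted(self.models)

    def get_flat(self):
        parts = [self.net.get_flat()]
        parts += [self.models[k].get_flat() for k in self.model_names]
        return np.concatenate(parts)

    def set_flat(self, flat):
        i = self.net.n_params
        self.net.set_flat(flat[:i])
        for k in self.model_names:
            m = self.models[k]
            m.set_flat(flat[i:i + m.n_params])
            i += m.n_params

    @property
    def n_params(self):
        return self.net.n_params + sum(m.n_params for m in self.models.values())


def data_loss_grads(net: MLP, tn_obs, un_obs, n_extra: int = 0):
    """Data loss and its flat gradient (padded with ``n_extra`` zeros for
    parameter-model weights, which the data term never touches)."""
    tn_obs = np.atleast_1d(np.asarray(tn_obs, dtype=float))
    if tn_obs.size == 0:
        raise ValueError("empty observation set")
    U, cache = net.forward(tn_obs[:, None], cache=True)
    diff = U - un_obs
    loss = float(np.mean(diff ** 2))
    gU = 2.0 * diff / diff.size
    g = MLP.flatten_grads(net.backward(cache, gU))
    if n_extra:
        g = np.concatenate([g, np.zeros(n_extra)])
    return loss, g


def _param_jacobian_fd(system, t, u, theta, j, h0=1e-6):
    """Central-difference d f / d theta_j, shape (n, V)."""
    h = h0 * (1.0 + np.abs(theta[:, j]))
    tp_, tm_ = theta.copy(), theta.copy()
    tp_[:, j] += h
    tm_[:, j] -= h
    return (system.rhs(t, u, tp_) - system.rhs(t, u, tm_)) / (2.0 * h[:, None])


def ode_loss_grads(net, system, spec, tp, models=None, weights=None,
                   per_equation: bool = False):
    """ODE losses and flat gradients over the full weight set.

    ``weights=None`` means the unweighted sum of per-equation losses; with
    ``per_equation=True`` a list of F flat gradients (one per raw
    ``L_f(i)``) is returned instead of a single combined gradient.
    """
    models = models or {}
    lf, r, ctx = _ode_forward(net, system, spec, tp, models, cache=True)
    t, tpn, U, Ud, u, theta, f, scale, net_cache, model_caches = ctx
    n = tpn.size
    V = system.state_dim
    J = system.state_jacobian(t, u, theta)
    half_width_u = (spec.state_upper - spec.state_lower) / 2.0
    learn = system.learnable_indices
    dfdth = {j: _param_jacobian_fd(system, t, u, theta, j) for j in learn} if models else {}
    model_names = sorted(models)

    def one_backward(w):
        gUd = (2.0 / n) * w[None, :] * r
        gf = -gUd * scale[None, :]
        gu = np.einsum("ni,nik->nk", gf, J)
        gU = gu * half_width_u[None, :]
        g = MLP.flatten_grads(net.backward(net_cache, gU, gUd))
        parts = [g]
        for name in model_names:
            j = next(jj for jj in learn if system.param_spec[jj].name == name)
            li = learn.index(j)  # position among learnable entries = bound index
            gth = np.einsum("ni,ni->n", gf, dfdth[j])
            gth_n = gth * (spec.param_upper[li] - spec.param_lower[li]) / 2.0
            raw, c = model_caches[name]
            parts.append(models[name].backward(c, gth_n))
        return np.concatenate(parts)

    F = V
    if per_equation:
        grads = [one_backward(np.eye(F)[i]) for i in range(F)]
        return lf, grads
    w = np.ones(F) if weights is None else np.asarray(weights, dtype=float)
    return lf, one_backward(w)
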