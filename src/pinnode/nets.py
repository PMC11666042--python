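"""Differentiable multilayer perceptron surrogates.

The PINN surrogates are small MLPs of a single (normalized-time) input.
Training needs three derivative quantities, and all are computed
analytically here:

* the network output ``U(t')``,
* its input derivative ``dU/dt'`` via forward-mode tangent propagation
  (the tangent of the scalar input is seeded with 1), and
* gradients of scalar losses with respect to every weight and bias,
  including losses that depend on ``dU/dt'`` — reverse mode propagated
  through the augmented (value, tangent) forward pass, which requires the
  activation's second derivative.

The hidden activation is the exact (erf-based) GELU, chosen for its
smoothness; weights use Glorot-uniform initialization, biases start at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = ["gelu", "gelu_prime", "gelu_second", "MLP", "Adam"]

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _phi(x):
    """Standard normal pdf."""
    return _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def gelu(x):
    """GELU(x) = x * Phi(x) with Phi the standard normal CDF."""
    return x * ndtr(x)


def gelu_prime(x):
    return ndtr(x) + x * _phi(x)


def gelu_second(x):
    return _phi(x) * (2.0 - x * x)


class MLP:
    """An MLP ``h0 = x; h_l = gelu(W_l h_{l-1} + b_l); out = W_L h_{L-1} + b_L``.

    Weight layout: ``weights[l]`` has shape (fan_in, fan_out); inputs are
    row vectors, so a layer computes ``h @ W + b``.  The final layer is
    linear.
    """

    def __init__(self, layer_sizes, rng: np.random.Generator | None = None):
        self.layer_sizes = list(int(s) for s in layer_sizes)
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least an input and an output size")
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        rng = rng or np.random.default_rng()
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @classmethod
    def from_spec(cls, n_hidden_layers: int, width: int, in_dim: int = 1,
                  out_dim: int = 1, rng=None) -> "MLP":
        sizes = [in_dim] + [width] * n_hidden_layers + [out_dim]
        return cls(sizes, rng)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    # -- parameter vector interface -----------------------------------------
    def get_flat(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.weights, self.biases):
            parts.append(W.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for l in range(self.n_layers):
            W, b = self.weights[l], self.biases[l]
            self.weights[l] = flat[i:i + W.size].reshape(W.shape)
            i += W.size
            self.biases[l] = flat[i:i + b.size].copy()
            i += b.size
        if i != flat.size:
            raise ValueError("flat vector size mismatch")

    @staticmethod
    def flatten_grads(grads) -> np.ndarray:
        parts = []
        for dW, db in grads:
            parts.append(dW.ravel())
            parts.append(db.ravel())
        return np.concatenate(parts)

    # -- forward passes -----------------------------------------------------
    def forward(self, x, cache: bool = False):
        """Plain forward pass.  ``x``: (n, in_dim).  Returns (n, out_dim)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        hs = [x]
        h = x
        last = self.n_layers - 1
        zs = []
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if l < last:
                zs.append(z)
                h = gelu(z)
            else:
                h = z
            hs.append(h)
        if cache:
            return h, {"hs": hs, "zs": zs, "tangent": False}
        return h

    def forward_with_tangent(self, x, cache: bool = False):
        """Forward pass carrying the input-derivative tangent.

        Returns ``(y, ydot)`` where ``ydot[j] = d y / d x`` at point j
        (scalar input assumed: in_dim must be 1).
        """
        if self.layer_sizes[0] != 1:
            raise ValueError("tangent propagation assumes a scalar input")
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        h = x
        hd = np.ones_like(x)
        hs, hds, zs, zds, sps = [x], [np.ones_like(x)], [], [], []
        last = self.n_layers - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            zd = hd @ W
            if l < last:
                sp = gelu_prime(z)
                zs.append(z)
                zds.append(zd)
                sps.append(sp)
                h = gelu(z)
                hd = sp * zd
            else:
                h, hd = z, zd
            hs.append(h)
            hds.append(hd)
        if cache:
            return h, hd, {"hs": hs, "hds": hds, "zs": zs, "zds": zds,
                           "sps": sps, "tangent": True}
        return h, hd

    # -- reverse mode -------------------------------------------------------
    def backward(self, cache, gy, gydot=None):
        """Gradients of a scalar loss w.r.t. weights and biases.

        ``gy`` is dLoss/d(output); ``gydot`` (optional) is dLoss/d(output
        tangent) and requires a cache from :meth:`forward_with_tangent`.
        Returns a list of (dW, db) pairs, one per layer.
        """
        hs, zs = cache["hs"], cache["zs"]
        with_t = gydot is not None
        if with_t and not cache["tangent"]:
            raise ValueError("tangent gradients need a tangent forward cache")
        if with_t:
            hds, zds = cache["hds"], cache["zds"]
        gh = np.asarray(gy, dtype=float)
        ghd = np.asarray(gydot, dtype=float) if with_t else None
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * self.n_layers
        last = self.n_layers - 1
        for l in range(last, -1, -1):
            W = self.weights[l]
            if l == last:
                gz = gh
                gzd = ghd
            else:
                z = zs[l]
                if with_t:
                    sp = cache["sps"][l]  # gelu'(z), saved by the tangent pass
                    gz = gh * sp + ghd * gelu_second(z) * zds[l]
                    gzd = ghd * sp
                else:
                    gz = gh * gelu_prime(z)
                    gzd = None
            dW = hs[l].T @ gz
            db = gz.sum(axis=0)
            if with_t and gzd is not None:
                dW = dW + hds[l].T @ gzd
            grads[l] = (dW, db)
            if l > 0:
                gh = gz @ W.T
                if with_t:
                    ghd = gzd @ W.T
        return grads

    def copy(self) -> "MLP":
        out = MLP.__new__(MLP)
        out.layer_sizes = list(self.layer_sizes)
        out.weights = [W.copy() for W in self.weights]
        out.biases = [b.copy() for b in self.biases]
        return out


@dataclass
class Adam:
    """Adam optimizer over a flat parameter vector."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def init(self, n: int) -> dict:
        return {"m": np.zeros(n), "v": np.zeros(n), "t": 0}

    def update(self, state: dict, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        state["t"] += 1
        t = state["t"]
        state["m"] = self.beta1 * state["m"] + (1 - self.beta1) * grad
        state["v"] = self.beta2 * state["v"] + (1 - self.beta2) * grad * grad
        mhat = state["m"] / (1 - self.beta1 ** t)
        vhat = state["v"] / (1 - self.beta2 ** t)
        return params - self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)
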