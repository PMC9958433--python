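"""Minimal dense neural-network engine.

A small fully connected architecture (ReLU hidden layers, linear output)
with hand-written reverse-mode gradients and an Adam optimizer.  Everything
is seeded through ``numpy.random.Generator`` instances passed in by the
caller, so fits are bit-reproducible.  The engine is deliberately tiny: the
package's training objectives (custom interval losses, Wasserstein critic
with gradient penalty) need gradients with respect to both parameters and
inputs, and for the gradient penalty a second differentiation of an input
gradient; all three modes are implemented here explicitly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["MLP", "Adam", "clip_grad_norm", "softplus", "sigmoid"]


def softplus(x: np.ndarray) -> np.ndarray:
    # overflow-safe log(1 + e^x)
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Fully connected network with ReLU hidden layers and a linear head.

    Parameters are plain numpy arrays (``W[k]`` of shape (fan_in, fan_out),
    ``b[k]`` of shape (fan_out,)), He-initialised from the supplied rng.
    ``hidden_sizes`` may be empty, giving a single linear layer.
    """

    def __init__(
        self,
        in_dim: int,
        hidden_sizes: Sequence[int],
        out_dim: int,
        rng: np.random.Generator,
    ) -> None:
        sizes = [int(in_dim), *[int(h) for h in hidden_sizes], int(out_dim)]
        if min(sizes) < 1:
            raise ValueError("layer sizes must be positive")
        self.sizes = sizes
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]

    # -- parameter access ---------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        for k in range(n):
            self.W[k][...] = params[k]
            self.b[k][...] = params[n + k]

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Forward pass; with ``want_cache`` also return activations/masks."""
        X = np.asarray(X, dtype=float)
        h = X
        hs = [X]
        masks = []
        n = len(self.W)
        for k in range(n):
            a = h @ self.W[k] + self.b[k]
            if k < n - 1:
                m = a > 0.0
                h = np.where(m, a, 0.0)
                masks.append(m)
            else:
                h = a
            hs.append(h)
        if want_cache:
            return h, (hs, masks)
        return h

    def backward(self, cache, dout: np.ndarray, want_input_grad: bool = False):
        """Reverse pass from d(loss)/d(output).

        Returns ``(dW, db, dX)`` where ``dX`` is None unless requested.
        """
        hs, masks = cache
        n = len(self.W)
        dW: list = [None] * n
        db: list = [None] * n
        g = np.asarray(dout, dtype=float)
        for k in range(n - 1, -1, -1):
            if k < n - 1:
                g = np.where(masks[k], g, 0.0)
            dW[k] = hs[k].T @ g
            db[k] = g.sum(axis=0)
            if k > 0 or want_input_grad:
                g = g @ self.W[k].T
        return dW, db, (g if want_input_grad else None)

    # -- forward-mode tangent (directional derivative wrt one input column) --
    def input_jvp(self, cache, column: int):
        """Directional derivative of each scalar output wrt input ``column``.

        Uses the cached forward pass.  Returns ``(g, tangents)`` where ``g``
        has shape (n, out_dim) and ``tangents`` are the per-layer tangent
        activations needed by :meth:`jvp_param_grads`.  ReLU masks are taken
        from the cache (their derivative wrt parameters is zero a.e., the
        standard convention for double backprop through piecewise-linear
        activations).
        """
        hs, masks = cache
        n = len(self.W)
        B = hs[0].shape[0]
        t = np.zeros_like(hs[0])
        t[:, column] = 1.0
        tangents = [t]
        for k in range(n - 1):
            t = (t @ self.W[k]) * masks[k]
            tangents.append(t)
        g = t @ self.W[n - 1]
        return g, tangents

    def jvp_param_grads(self, cache, tangents, dP_dg: np.ndarray):
        """Gradients of a scalar function P of the jvp output wrt weights.

        ``dP_dg`` is d(P)/d(g) of shape (n, out_dim).  Biases receive no
        gradient from the tangent path.  ReLU masks are treated as constant
        (exact a.e.).
        """
        hs, masks = cache
        n = len(self.W)
        dW = [np.zeros_like(Wk) for Wk in self.W]
        dW[n - 1] = tangents[n - 1].T @ dP_dg
        u = dP_dg @ self.W[n - 1].T
        for k in range(n - 2, -1, -1):
            q = np.where(masks[k], u, 0.0)
            dW[k] += tangents[k].T @ q
            u = q @ self.W[k].T
        return dW


class Adam:
    """Adam optimizer over a list of parameter arrays (in-place updates)."""

    def __init__(
        self,
        params_like: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params_like]
        self.v = [np.zeros_like(p) for p in params_like]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if total > max_norm > 0.0:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total
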