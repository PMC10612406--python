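"""Minimal NumPy neural-network primitives with hand-written gradients.

No deep-learning framework is assumed: the transformer and the CNN in
this package run on these float64 building blocks. Every backward
function here is exercised by finite-difference gradient checks in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact Gaussian-error linear unit: ``x * Phi(x)``."""
    return x * ndtr(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return ndtr(x) + x * np.exp(-0.5 * x * x) / _SQRT_2PI


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layernorm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray,
                      eps: float = 1e-12):
    """Normalize over the last axis; returns (y, cache)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    y = g * xhat + b
    return y, (xhat, inv, g)


def layernorm_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = dxhat.mean(axis=-1, keepdims=True)
    mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02,
                     bound: float = 2.0) -> np.ndarray:
    """Normal(0, std) truncated at ``bound`` standard deviations,
    drawn by resampling (BERT-style initializer)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > bound * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > bound * std
    return out


class Adam:
    """Adam with optional linear warmup on the learning rate."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 warmup_steps: int = 0, total_steps: int | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup_steps = warmup_steps
        self.total_steps = total_steps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def current_lr(self) -> float:
        if self.warmup_steps and self.t <= self.warmup_steps:
            return self.lr * self.t / max(1, self.warmup_steps)
        return self.lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr = self.current_lr()
        for k, gval in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gval
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gval * gval
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
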