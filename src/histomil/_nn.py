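"""Minimal neural-network primitives shared by the tile and slide models.

Parameters live in plain dicts of :class:`numpy.ndarray`; every model computes
its own gradients analytically (verified against finite differences in the
test suite) and updates them with the Adam optimizer below.  All randomness is
funnelled through :func:`numpy.random.default_rng` generators created from an
explicit seed, so training is bit-reproducible.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

Params = Dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, shifted for stability."""
    z = x - np.max(x, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross entropy between probabilities ``p`` and labels ``y``."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization for a (fan_in, fan_out) weight."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def affine_init(rng: np.random.Generator, fan_in: int, fan_out: int,
                prefix: str) -> Params:
    return {f"{prefix}_W": glorot(rng, fan_in, fan_out),
            f"{prefix}_b": np.zeros(fan_out)}


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: Params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def finite_difference_grads(loss_fn: Callable[[Params], float],
                            params: Params, h: float = 1e-6) -> Params:
    """Central finite-difference gradients; the test-suite oracle for backprop."""
    grads = {}
    for k, arr in params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            lp = loss_fn(params)
            flat[i] = orig - h
            lm = loss_fn(params)
            flat[i] = orig
            gflat[i] = (lp - lm) / (2 * h)
        grads[k] = g
    return grads
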