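"""Shared numerical primitives: activations, initialization, Adam.

All networks in this package are small fixed-architecture multilayer
perceptrons, so forward and backward passes are written explicitly in numpy
rather than through a general autodiff framework.
"""

from __future__ import annotations

import numpy as np


def leaky_relu(v: np.ndarray, slope: float) -> np.ndarray:
    return np.where(v > 0, v, slope * v)


def leaky_relu_grad(v: np.ndarray, slope: float) -> np.ndarray:
    return np.where(v > 0, 1.0, slope)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Variance-scaled symmetric (Glorot) uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        """In-place descent step on every named parameter with a gradient."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
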