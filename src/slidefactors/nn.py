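"""Minimal neural-network primitives: single-hidden-layer MLPs with manual
backpropagation and an Adam optimizer, all in NumPy.

The graph model needs only small perceptrons (message networks and per-layer
heads), so a compact hand-written implementation keeps the package
CPU-friendly and bitwise reproducible.  Gradients are exercised against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """x @ W1 + b1 -> activation -> @ W2 + b2 (He-initialised, seeded).

    ``activation`` is "relu" (default) or "identity"; the identity makes the
    perceptron a smooth factored linear map, which trains to precise weight
    alignment where rectified random features cannot.
    """

    def __init__(self, d_in: int, hidden: int, d_out: int,
                 rng: np.random.Generator, zero_output: bool = False,
                 output_scale: float = 1.0, activation: str = "relu"):
        if activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, hidden))
        # small positive bias keeps hidden units off the ReLU kink for the
        # all-zero inputs that sum aggregation produces at sparse nodes
        self.b1 = np.full(hidden, 0.01)
        if zero_output:
            # heads start at exactly zero score: summing scores over hundreds
            # of nodes amplifies any random initial output into slide-score
            # noise that swamps the ranking signal, so score growth is left
            # entirely gradient-driven
            self.W2 = np.zeros((hidden, d_out))
        else:
            self.W2 = output_scale * rng.normal(
                0.0, np.sqrt(2.0 / hidden), size=(hidden, d_out)
            )
        self.b2 = np.zeros(d_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def set_params(self, params: list[np.ndarray]) -> None:
        self.W1, self.b1, self.W2, self.b2 = [np.array(p) for p in params]

    def forward(self, x: np.ndarray):
        z1 = x @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0) if self.activation == "relu" else z1
        out = a1 @ self.W2 + self.b2
        return out, (x, z1, a1)

    def backward(self, cache, g_out: np.ndarray):
        """Returns (grad wrt input, [gW1, gb1, gW2, gb2])."""
        x, z1, a1 = cache
        gW2 = a1.T @ g_out
        gb2 = g_out.sum(axis=0)
        ga1 = g_out @ self.W2.T
        gz1 = ga1 * (z1 > 0) if self.activation == "relu" else ga1
        gW1 = x.T @ gz1
        gb1 = gz1.sum(axis=0)
        gx = gz1 @ self.W1.T
        return gx, [gW1, gb1, gW2, gb2]


class Adam:
    """Adaptive-momentum optimizer with additive (L2) weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + self.wd * p
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def clone_params(params: list[np.ndarray]) -> list[np.ndarray]:
    return [np.array(p) for p in params]


def zeros_like_params(params: list[np.ndarray]) -> list[np.ndarray]:
    return [np.zeros_like(p) for p in params]


def add_params(acc: list[np.ndarray], extra: list[np.ndarray]) -> None:
    for a, e in zip(acc, extra):
        a += e
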