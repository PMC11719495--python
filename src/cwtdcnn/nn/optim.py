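"""Stochastic optimizers updating parameter arrays in place."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "RMSprop", "make_optimizer"]


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class RMSprop:
    """RMSprop with running squared-gradient average (rho=0.9, eps=1e-7)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 2e-4,
                 rho: float = 0.9, eps: float = 1e-7):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr, self.rho, self.eps = learning_rate, rho, eps
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v += (1 - self.rho) * (g * g - v)
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, params: list[np.ndarray], learning_rate: float):
    if name == "adam":
        return Adam(params, learning_rate)
    if name == "rmsprop":
        return RMSprop(params, learning_rate)
    raise ValueError(f"unsupported optimizer {name!r} (use 'adam' or 'rmsprop')")
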