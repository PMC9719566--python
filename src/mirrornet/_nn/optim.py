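"""First-order optimisers over flat lists of parameter arrays."""

from __future__ import annotations

import numpy as np


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their joint L2 norm is at most
    ``max_norm``; returns the pre-clip norm."""
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads)))
    if max_norm > 0 and total > max_norm:
        scale = np.float32(max_norm / (total + 1e-12))
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain stochastic gradient descent (optional momentum)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p in params] if momentum else None

    def step(self, grads: list[np.ndarray]) -> None:
        if self.vel is None:
            for p, g in zip(self.params, grads):
                p -= self.lr * g
        else:
            for p, g, v in zip(self.params, grads, self.vel):
                v *= self.momentum
                v -= self.lr * g
                p += v
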