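"""Optimizers for the numpy engine: SGD (nesterov momentum) and AdamW."""

from __future__ import annotations

from typing import List

import numpy as np

from .layers import Param


class SGD:
    """Stochastic gradient descent with (nesterov) momentum.

    Defaults follow the tumor-stage recipe used throughout the package:
    learning rate 1e-3, momentum 0.99, nesterov update.
    """

    def __init__(self, params: List[Param], lr=1e-3, momentum=0.99,
                 nesterov=True, weight_decay=0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            upd = g + self.momentum * v if self.nesterov else v
            p.data -= (self.lr * upd).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class AdamW:
    """Adam with decoupled weight decay (organ-stage default, lr 3.5e-4)."""

    def __init__(self, params: List[Param], lr=3.5e-4, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=1e-2):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                upd = upd + self.weight_decay * p.data
            p.data -= (self.lr * upd).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def polynomial_lr(base_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """nnUNet-style polynomial decay schedule."""
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * (1.0 - frac) ** power
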