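"""Optimizers and the exponential learning-rate schedule.

RMSprop is the package default (a momentum-free adaptive method); Adam is
available as an alternative.  ``exponential_lr`` implements
lr(epoch) = initial_lr * gamma**epoch, the decay schedule used for every
training loop, starting from the default initial rate of 0.001.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["RMSprop", "Adam", "exponential_lr"]


def exponential_lr(epoch: int, initial_lr: float = 1e-3, gamma: float = 0.98) -> float:
    """Exponentially decayed learning rate at a given epoch (0-based)."""
    if epoch < 0:
        raise ValueError(f"epoch must be non-negative, got {epoch}")
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    if initial_lr <= 0:
        raise ValueError(f"initial_lr must be positive, got {initial_lr}")
    return initial_lr * gamma**epoch


class RMSprop:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, alpha: float = 0.9,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.alpha
            s += (1.0 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
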