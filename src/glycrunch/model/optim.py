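"""AdamW optimizer, plateau learning-rate schedule and early stopping."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "PlateauScheduler"]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 2e-5,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p.value
            )


class PlateauScheduler:
    """Reduce the learning rate when the monitored loss stops improving and
    signal early stopping after a longer stall."""

    def __init__(
        self,
        optimizer: AdamW,
        factor: float = 0.2,
        patience: int = 4,
        early_stop: int = 12,
        min_delta: float = 1e-6,
    ):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.early_stop = early_stop
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> bool:
        """Record an epoch loss; returns True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale and self.stale % self.patience == 0:
            self.opt.lr *= self.factor
        return self.stale >= self.early_stop
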