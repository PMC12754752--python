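"""Optimizers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Cut the learning rate by ``factor`` when the monitored loss has not
    improved by more than ``threshold`` (relative) for ``patience`` epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 2,
                 threshold: float = 1e-3, min_lr: float = 1e-7):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best * (1 - self.threshold):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
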