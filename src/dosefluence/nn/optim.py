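"""Adam optimizer and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params: dict[str, Param], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored value has
    not improved (relatively, by ``threshold``) for ``patience`` epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.7, patience: int = 4,
                 threshold: float = 1e-4, min_lr: float = 0.0):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0
        self.n_reductions = 0

    def step(self, metric: float) -> bool:
        """Record one epoch's metric; returns True if the lr was reduced."""
        if metric < self.best * (1.0 - self.threshold):
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.n_reductions += 1
            self.bad_epochs = 0
            return True
        return False
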