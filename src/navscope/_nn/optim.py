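"""Optimizers and learning-rate schedules for the numpy decoders."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam; set ``decoupled=True`` for AdamW-style weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decoupled: bool = False):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def AdamW(params, lr: float = 1e-4, weight_decay: float = 1e-4, **kw):
    return Adam(params, lr=lr, weight_decay=weight_decay, decoupled=True, **kw)


class CosineAnnealingLR:
    """Cosine decay of the optimizer learning rate over ``t_max`` epochs."""

    def __init__(self, opt: Adam, t_max: int, eta_min: float = 0.0):
        self.opt = opt
        self.base = opt.lr
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.epoch = 0

    def step(self):
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.opt.lr = self.eta_min + 0.5 * (self.base - self.eta_min) * (
            1 + np.cos(np.pi * frac))


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when a metric stops improving."""

    def __init__(self, opt: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6):
        self.opt = opt
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
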