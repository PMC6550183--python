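"""Adam optimizer and plateau-driven learning-rate scheduling.

The schedule mirrors the common "reduce LR on plateau" policy: whenever the
validation loss fails to improve by more than ``min_delta`` for
``plateau_patience`` consecutive epochs, the learning rate is multiplied by
``plateau_factor`` (0.2 here); training stops once ``early_stop_patience``
epochs pass without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Param


@dataclass
class TrainSchedule:
    initial_lr: float = 1e-3
    plateau_factor: float = 0.2
    plateau_patience: int = 3
    min_delta: float = 1e-4
    max_epochs: int = 50
    batch_size: int = 16
    early_stop_patience: int = 9
    beta1: float = 0.9
    beta2: float = 0.999


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class PlateauTracker:
    """Tracks validation loss; decides LR reductions and early stopping."""

    def __init__(self, schedule: TrainSchedule):
        self.s = schedule
        self.best = np.inf
        self.wait = 0
        self.since_reduce = 0

    def update(self, val_loss: float) -> tuple[bool, bool]:
        """Returns (reduce_lr_now, stop_now)."""
        if val_loss < self.best - self.s.min_delta:
            self.best = val_loss
            self.wait = 0
            self.since_reduce = 0
            return False, False
        self.wait += 1
        self.since_reduce += 1
        reduce = self.since_reduce >= self.s.plateau_patience
        if reduce:
            self.since_reduce = 0
        stop = self.wait >= self.s.early_stop_patience
        return reduce, stop


@dataclass
class History:
    """Per-epoch training log."""
    epochs: list = field(default_factory=list)

    def log(self, **kv):
        self.epochs.append(kv)

    def trace(self, key):
        return [e[key] for e in self.epochs]

    def to_json(self):
        return {"epochs": self.epochs}
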