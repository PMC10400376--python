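"""Optimizers and learning-rate schedules.

AdamW uses decoupled weight decay (decay applied directly to the weights,
scaled by the current learning rate, never through the moment estimates).
Lion keeps a single momentum buffer and steps by the sign of an interpolated
gradient; per its authors' guidance the package's training harness runs Lion
with a 10x smaller learning rate and a 10x larger weight decay than AdamW.

The one-cycle schedule has exactly two cosine phases: a rise from
max_lr/div_start to max_lr over the warmup fraction of steps, then a fall to
max_lr/div_final, continuous at the junction.
"""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "Lion", "one_cycle_lr", "ReduceLROnPlateau"]


class Optimizer:
    def __init__(self, params: list[Param], lr: float, weight_decay: float):
        self.param_list = params
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def zero_grad(self) -> None:
        for p in self.param_list:
            p.grad[...] = 0.0

    def step(self) -> None:
        raise NotImplementedError


class AdamW(Optimizer):
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.param_list, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            if p.decay and self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Lion(Optimizer):
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.99),
        weight_decay: float = 0.1,
    ):
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        b1, b2 = self.b1, self.b2
        for p, m in zip(self.param_list, self.m):
            g = p.grad
            update = np.sign(b1 * m + (1.0 - b1) * g)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
            m += (1.0 - b2) * (g - m)


def one_cycle_lr(
    step: int,
    total_steps: int,
    max_lr: float,
    warmup_fraction: float = 0.3,
    div_start: float = 25.0,
    div_final: float = 1e4,
) -> float:
    """Two-phase cosine one-cycle learning rate at a given step.

    Phase 1 (first ``warmup_fraction`` of steps) rises from max_lr/div_start
    to max_lr on a cosine; phase 2 decays from max_lr to max_lr/div_final.
    """
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    rise_steps = max(int(round(warmup_fraction * total_steps)), 1)
    lo, hi = max_lr / div_start, max_lr
    if step < rise_steps:
        t = step / max(rise_steps - 1, 1)
        return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * t))
    fall_steps = total_steps - rise_steps
    lo_final = max_lr / div_final
    t = (step - rise_steps + 1) / max(fall_steps, 1)
    return lo_final + (hi - lo_final) * 0.5 * (1.0 + np.cos(np.pi * t))


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(
        self,
        optimizer: Optimizer,
        factor: float = 0.1,
        patience: int = 3,
        min_lr: float = 1e-7,
    ):
        if not 0 < factor < 1:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, metric: float) -> float:
        """Update with a validation metric (lower is better); returns the lr."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.stale = 0
        return self.optimizer.lr
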