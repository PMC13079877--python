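"""Gradient-based optimizers and the one-cycle learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    """Adam with optional decoupled weight decay (AdamW when wd > 0)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_mask: list[bool] | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        # decay weight matrices only by default; biases and scalar
        # parameters (e.g. learnable Lipschitz constants) are exempt
        self.decay_mask = (
            [p.ndim >= 2 for p in self.params] if decay_mask is None else list(decay_mask)
        )
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def step(self, grads: list[Tensor]):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay and self.decay_mask[i]:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        super().__init__(params, lr=lr, betas=betas, eps=eps, weight_decay=weight_decay)


class OneCycleLR:
    """One-cycle schedule: cosine warm-up to max_lr, cosine anneal to ~0.

    Mirrors the common default parameterization: initial lr = max_lr /
    div_factor, warm-up over ``pct_start`` of the run, final lr = initial /
    final_div_factor.
    """

    def __init__(
        self,
        optimizer,
        max_lr: float,
        total_steps: int,
        pct_start: float = 0.3,
        div_factor: float = 25.0,
        final_div_factor: float = 1e4,
    ):
        self.opt = optimizer
        self.max_lr = max_lr
        self.total_steps = max(1, total_steps)
        self.up_steps = max(1, int(pct_start * self.total_steps))
        self.down_steps = max(1, self.total_steps - self.up_steps)
        self.initial_lr = max_lr / div_factor
        self.final_lr = self.initial_lr / final_div_factor
        self.step_num = 0
        self.opt.lr = self.initial_lr

    @staticmethod
    def _cos(a: float, b: float, frac: float) -> float:
        return b + (a - b) * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self):
        self.step_num += 1
        s = min(self.step_num, self.total_steps)
        if s <= self.up_steps:
            lr = self._cos(self.initial_lr, self.max_lr, s / self.up_steps)
        else:
            lr = self._cos(self.max_lr, self.final_lr, (s - self.up_steps) / self.down_steps)
        self.opt.lr = lr
        return lr
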