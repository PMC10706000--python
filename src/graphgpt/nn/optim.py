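"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 6e-4,
        betas: tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * g
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if self.weight_decay and p.data.ndim >= 2:  # no decay on biases/gains
                p.data = p.data - lr * self.weight_decay * p.data
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float, warmup_frac: float = 0.1) -> float:
    """Linear warm-up followed by cosine decay to 10% of base_lr."""
    warmup = max(1, int(total_steps * warmup_frac))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    progress = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * (0.1 + 0.9 * 0.5 * (1.0 + math.cos(math.pi * min(progress, 1.0))))
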