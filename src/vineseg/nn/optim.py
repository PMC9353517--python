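"""Stochastic gradient descent with momentum and decoupled-from-nothing
classic L2 weight decay (decay added to the gradient, as in the usual SGD
recipe for detection models)."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_grad_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_grad_norm = clip_grad_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _total_norm(self) -> float:
        sq = 0.0
        for p in self.params:
            if p.grad is not None:
                sq += float((p.grad.astype(np.float64) ** 2).sum())
        return float(np.sqrt(sq))

    def step(self):
        scale = 1.0
        if self.clip_grad_norm is not None:
            norm = self._total_norm()
            if norm > self.clip_grad_norm:
                scale = self.clip_grad_norm / (norm + 1e-12)
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
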