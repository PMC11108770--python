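"""Adam with decoupled weight decay, operating on a Module's parameter dict.

Decay is applied to matrix-shaped parameters only (weights), never to
biases, gains or embedding-free scalars, following common CLIP practice.
"""
from __future__ import annotations

import numpy as np

from .layers import Module, Tensor


class AdamW:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.98), eps: float = 1e-8,
                 weight_decay: float = 0.2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def _decayed(self, name: str, p: Tensor) -> bool:
        return p.data.ndim >= 2

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decayed(k, p):
                upd = upd + self.weight_decay * p.data
            p.data = p.data - self.lr * upd

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


__all__ = ["AdamW"]
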