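"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autograd import Tensor


class AdamW:
    """AdamW with decoupled weight decay and optional per-parameter decay
    flags (norm/bias/embedding parameters are conventionally excluded)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05, decay_flags=None):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.decay_flags = (list(decay_flags) if decay_flags is not None
                            else [True] * len(self.params))
        if len(self.decay_flags) != len(self.params):
            raise ValueError("decay_flags length mismatch")
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v, decay in zip(self.params, self.m, self.v,
                                  self.decay_flags):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            wd = self.weight_decay if decay else 0.0
            p.data = p.data - self.lr * (update + wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
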