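"""Adam optimiser (L2-coupled weight decay, as in the classic formulation)."""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Adam:
    def __init__(self, params, lr: float = 1e-4, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = _F32(self.b1), _F32(self.b2)
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        lr = _F32(self.lr)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + _F32(self.weight_decay) * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / _F32(bc1)
            vhat = v / _F32(bc2)
            p.data -= lr * mhat / (np.sqrt(vhat) + _F32(self.eps))
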