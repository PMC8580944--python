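"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np


class SGD:
    """``v <- mu v + g``; ``p <- p - lr v``. Frozen parameters are skipped."""

    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if not p.requires_grad or p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
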