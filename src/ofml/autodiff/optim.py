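"""Optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import DEFAULT_DTYPE
from .nn import Parameter


class Adam:
    """Adam with L2 weight decay added to the gradient.

    ``beta1`` is the first-moment decay — the closest analogue of the
    "momentum" setting reported for Adam-based training recipes.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros(p.shape, dtype=DEFAULT_DTYPE) for p in self.params]
        self._v = [np.zeros(p.shape, dtype=DEFAULT_DTYPE) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
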