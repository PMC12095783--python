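"""Optimizers for the numpy networks.

Adagrad is the default throughout the package (it gave the best
accuracy in the hyperparameter sweep that motivated these defaults,
at a learning rate of 0.003).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor]):
        self.params = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class Adagrad(Optimizer):
    """Adagrad: per-parameter learning rates from accumulated squared
    gradients; well suited to the sparse, small-batch updates here."""

    def __init__(self, params: list[Tensor], lr: float = 0.003, eps: float = 1e-10):
        super().__init__(params)
        self.lr = lr
        self.eps = eps
        self.accum = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, g2 in zip(self.params, self.accum):
            if p.grad is None:
                continue
            g2 += p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(g2) + self.eps)


class SGD(Optimizer):
    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.0):
        super().__init__(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
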