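"""Stochastic gradient descent with momentum (the training optimizer)."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["SGD"]


class SGD:
    """SGD with classical momentum (0.9 by default) and optional global-norm
    gradient clipping for training stability on long inputs."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        momentum: float = 0.9,
        clip_norm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        for p, v, g in zip(self.params, self._velocity, grads):
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
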