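"""Optimizers and the warm-up / polynomial-decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    """SGD with classical or Nesterov momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 nesterov: bool = False, weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v *= self.momentum
                v += g
                g = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * g


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1**self._t
        bc2 = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


def warmup_poly_lr(iteration: int, total_iterations: int, base_lr: float,
                   warmup_iterations: int, warmup_start_lr: float = 1e-6,
                   gamma: float = 0.9) -> float:
    """Linear warm-up followed by polynomial decay.

    The learning rate climbs linearly from ``warmup_start_lr`` to ``base_lr``
    over the warm phase, then decays as ``base_lr * (1 - t)**gamma`` where
    ``t`` is the fraction of the post-warm-up schedule elapsed.
    """
    if total_iterations <= 0:
        raise ValueError("total_iterations must be positive")
    if warmup_iterations > 0 and iteration < warmup_iterations:
        frac = iteration / warmup_iterations
        return warmup_start_lr + frac * (base_lr - warmup_start_lr)
    span = max(total_iterations - warmup_iterations, 1)
    t = min((iteration - warmup_iterations) / span, 1.0)
    return base_lr * (1.0 - t) ** gamma
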