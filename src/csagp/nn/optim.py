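"""Optimizers and losses for the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "cross_entropy"]


class Adam:
    """Adam with (classic) L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cross_entropy(logits: Tensor, target: int | np.ndarray) -> Tensor:
    """Mean cross-entropy; logits (C,) with int target or (B, C) with (B,)."""
    logp = logits.log_softmax(axis=-1)
    if logits.ndim == 1:
        return -logp[int(target)]
    target = np.asarray(target, dtype=int)
    picked = logp[np.arange(len(target)), target]
    return -picked.mean()
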