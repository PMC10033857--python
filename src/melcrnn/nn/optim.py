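"""Optimisation utilities: Adam and the fused softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "softmax_cross_entropy", "softmax"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy (natural log) between softmax(logits) and integer labels.

    Fused for numerical stability; gradient is (p - onehot) / batch.
    """
    labels = np.asarray(labels)
    p = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    losses = -np.log(np.maximum(p[np.arange(n), labels], eps))
    out_data = losses.mean()

    def backward(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        logits._accumulate((g * gp / n).astype(logits.data.dtype))

    return Tensor._make(np.asarray(out_data), (logits,), backward)


class Adam:
    """Adam with the standard bias correction; defaults beta=(0.9, 0.999), eps=1e-8."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
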