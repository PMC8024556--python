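"""Nadam optimizer (Adam with Nesterov momentum) and gradient clipping."""

from __future__ import annotations

import numpy as np

__all__ = ["Nadam", "global_norm", "clip_by_global_norm"]


def global_norm(grads: list[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g * g).sum()) for g in grads)))


def clip_by_global_norm(grads: list[np.ndarray], clip: float) -> list[np.ndarray]:
    """Rescale all gradients jointly so their global norm is at most ``clip``."""
    norm = global_norm(grads)
    if norm > clip:
        scale = clip / norm
        return [g * scale for g in grads]
    return grads


class Nadam:
    """Adam with Nesterov momentum (Dozat 2016 formulation).

    Defaults mirror the usual framework defaults: β1 = 0.9, β2 = 0.999,
    ε = 1e-7; the learning rate used throughout this package is 0.002.
    """

    def __init__(self, lr: float = 0.002, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        """Update ``params`` in place from matching ``grads``."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(k, np.zeros_like(p))
            v = self._v.setdefault(k, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (self.t + 1)) + (1 - b1) * g / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
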