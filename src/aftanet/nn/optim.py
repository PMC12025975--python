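"""AdamW optimizer and exponential-moving-average parameter updates."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["AdamW", "ema_update"]


class AdamW:
    """Adam with decoupled weight decay.

    `lr_scales` maps parameter names to multiplicative learning-rate factors
    (used for layer-wise decay); unnamed parameters use factor 1.
    """

    def __init__(self, params: dict[str, Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 lr_scales: dict[str, float] | None = None):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_scales = lr_scales or {}
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            lr = self.lr * self.lr_scales.get(name, 1.0)
            m = self._m[name] = b1 * self._m[name] + (1.0 - b1) * p.grad
            v = self._v[name] = b2 * self._v[name] + (1.0 - b2) * p.grad ** 2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            # decoupled decay: applied directly to weights, scaled by lr
            p.data = p.data - lr * update - lr * self.weight_decay * p.data


def ema_update(online: dict[str, np.ndarray], target: dict[str, np.ndarray],
               m: float) -> dict[str, np.ndarray]:
    """target <- m * target + (1 - m) * online, key by key."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("momentum coefficient must lie in [0, 1]")
    if set(online) != set(target):
        raise ValueError("parameter trees mismatched")
    return {k: m * target[k] + (1.0 - m) * online[k] for k in online}
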