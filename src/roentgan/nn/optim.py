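"""Adam optimizer with inverse-time or exponential learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with a per-step learning-rate schedule.

    ``decay`` follows the legacy Keras convention: with
    ``schedule="inverse_time"`` the effective rate at update t is
    ``lr / (1 + decay * t)``; with ``schedule="exponential"`` it is
    ``lr * exp(-decay * t)``.
    """

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.9, decay: float = 1e-4, eps: float = 1e-7,
                 schedule: str = "inverse_time"):
        if schedule not in ("inverse_time", "exponential"):
            raise ValueError(f"unknown schedule {schedule!r}")
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.decay = decay
        self.eps = eps
        self.schedule = schedule
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def current_lr(self) -> float:
        if self.schedule == "inverse_time":
            return self.lr / (1.0 + self.decay * self.t)
        return self.lr * float(np.exp(-self.decay * self.t))

    def step(self) -> None:
        lr_t = self.current_lr()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr_t * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
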