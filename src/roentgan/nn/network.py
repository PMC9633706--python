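"""Sequential container with parameter counting and state round-tripping."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param


class Sequential:
    def __init__(self, layers: list[Layer], name: str = "net"):
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Propagate a gradient back through every layer; returns d(loss)/d(input)."""
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def trainable_params(self) -> list[Param]:
        return [p for p in self.params() if p.trainable]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def count_params(self) -> dict[str, int]:
        total = sum(p.size for p in self.params())
        trainable = sum(p.size for p in self.params() if p.trainable)
        return {
            "total": total,
            "trainable": trainable,
            "non_trainable": total - trainable,
        }

    # -- state round-trip -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for p in self.params():
            if p.name in state:
                raise ValueError(f"duplicate parameter name {p.name!r}")
            state[p.name] = p.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r}")
            value = np.asarray(state[p.name], dtype=np.float32)
            if value.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name!r}: {value.shape} vs {p.value.shape}")
            p.value[...] = value
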