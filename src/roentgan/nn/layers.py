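"""Minimal reverse-mode neural-network layers on NumPy arrays.

All image tensors are NHWC float32. Every layer implements ``forward`` and
``backward``; ``backward`` both accumulates parameter gradients (into
``Param.grad``) and returns the gradient with respect to its input, so a full
backward pass yields the input gradient needed for the WGAN gradient penalty.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2D",
    "BatchNorm",
    "ELU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Flatten",
    "Reshape",
    "UpSampling2D",
    "MaxPool2D",
    "ZeroPad2D",
    "Cropping2D",
]


class Param:
    """A weight array with its accumulated gradient and trainability flag."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    name = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, use_bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.w = Param(f"{name}.w", _glorot(rng, (in_features, out_features),
                                            in_features, out_features))
        self.b = Param(f"{name}.b", np.zeros(out_features)) if use_bias else None
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


def _same_padding(in_size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-in_size // stride)  # ceil
    total = max((out - 1) * stride + kernel - in_size, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution (cross-correlation), NHWC, 'same' or 'valid' padding."""

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int = 1,
                 padding: str = "same", use_bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.name = name
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = kernel * kernel * in_channels
        fan_out = kernel * kernel * filters
        self.w = Param(f"{name}.w",
                       _glorot(rng, (kernel, kernel, in_channels, filters), fan_in, fan_out))
        self.b = Param(f"{name}.b", np.zeros(filters)) if use_bias else None
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None
        self._pads: tuple | None = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _pad_amounts(self, h: int, w: int):
        if self.padding == "same":
            return _same_padding(h, self.kernel, self.stride), _same_padding(w, self.kernel, self.stride)
        return (0, 0), (0, 0)

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        k, s = self.kernel, self.stride
        (pt, pb), (pl, pr) = self._pad_amounts(h, w)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        hp, wp = xp.shape[1], xp.shape[2]
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        cols = np.empty((n, oh, ow, k, k, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
        self._cols = cols.reshape(n * oh * ow, k * k * c)
        self._x_shape = x.shape
        self._pads = (pt, pb, pl, pr, oh, ow)
        y = self._cols @ self.w.value.reshape(k * k * c, -1)
        y = y.reshape(n, oh, ow, -1)
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad):
        n, h, w, c = self._x_shape
        k, s = self.kernel, self.stride
        pt, pb, pl, pr, oh, ow = self._pads
        f = grad.shape[-1]
        g2 = grad.reshape(n * oh * ow, f)
        self.w.grad += (self._cols.T @ g2).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value.reshape(k * k * c, f).T).reshape(n, oh, ow, k, k, c)
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm(Layer):
    """Batch normalization over the last axis (features/channels).

    Moving mean/variance are non-trainable parameters (they count toward the
    model's total but not trainable parameter tally).
    """

    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.99,
                 name: str = "bn"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(num_features))
        self.beta = Param(f"{name}.beta", np.zeros(num_features))
        self.moving_mean = Param(f"{name}.moving_mean", np.zeros(num_features), trainable=False)
        self.moving_var = Param(f"{name}.moving_var", np.ones(num_features), trainable=False)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value[...] = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value[...] = m * self.moving_var.value + (1 - m) * var
        else:
            mean = self.moving_mean.value
            var = self.moving_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not training:
            return (g * inv).astype(np.float32)
        nred = np.prod([shape[a] for a in axes])
        dxhat = g
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        return dx.astype(np.float32)


class ELU(Layer):
    def __init__(self, alpha: float = 0.2, name: str = "elu"):
        self.name = name
        self.alpha = alpha
        self._y = None
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        y = np.where(self._mask, x, self.alpha * np.expm1(x)).astype(np.float32)
        self._y = y
        return y

    def backward(self, grad):
        return grad * np.where(self._mask, 1.0, self._y + self.alpha).astype(np.float32)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return grad * self._mask


class Tanh(Layer):
    name = "tanh"

    def forward(self, x, training=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    name = "sigmoid"

    def forward(self, x, training=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when not training. Mask comes from ``rng``."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.name = name
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple, name: str = "reshape"):
        self.name = name
        self.shape = shape

    def forward(self, x, training=False, rng=None):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(self._in)


class UpSampling2D(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2, name: str = "upsample"):
        self.name = name
        self.factor = factor

    def forward(self, x, training=False, rng=None):
        f = self.factor
        return x.repeat(f, axis=1).repeat(f, axis=2)

    def backward(self, grad):
        f = self.factor
        n, h, w, c = grad.shape
        return grad.reshape(n, h // f, f, w // f, f, c).sum(axis=(2, 4))


class MaxPool2D(Layer):
    """Non-overlapping max pooling ('valid': trailing rows/cols dropped)."""

    def __init__(self, size: int = 2, name: str = "maxpool"):
        self.name = name
        self.size = size

    def forward(self, x, training=False, rng=None):
        s = self.size
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        xt = x[:, :oh * s, :ow * s, :].reshape(n, oh, s, ow, s, c)
        y = xt.max(axis=(2, 4))
        self._cache = (x.shape, xt, y)
        return y

    def backward(self, grad):
        shape, xt, y = self._cache
        s = self.size
        n, oh, _, ow, _, c = xt.shape
        mask = (xt == y[:, :, None, :, None, :])
        # split gradient among ties so totals are conserved
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxt = mask * (grad[:, :, None, :, None, :] / counts)
        dx = np.zeros(shape, dtype=np.float32)
        dx[:, :oh * s, :ow * s, :] = dxt.reshape(n, oh * s, ow * s, c)
        return dx


class ZeroPad2D(Layer):
    def __init__(self, pad: int, name: str = "zeropad"):
        self.name = name
        self.pad = pad

    def forward(self, x, training=False, rng=None):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def backward(self, grad):
        p = self.pad
        return grad[:, p:-p or None, p:-p or None, :]


class Cropping2D(Layer):
    def __init__(self, crop: int, name: str = "crop"):
        self.name = name
        self.crop = crop

    def forward(self, x, training=False, rng=None):
        c = self.crop
        self._shape = x.shape
        if c == 0:
            return x
        return x[:, c:-c, c:-c, :]

    def backward(self, grad):
        c = self.crop
        if c == 0:
            return grad
        dx = np.zeros(self._shape, dtype=np.float32)
        dx[:, c:-c, c:-c, :] = grad
        return dx
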