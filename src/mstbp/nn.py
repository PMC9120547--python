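"""Minimal 1-D neural-network engine in NumPy.

Implements exactly the layer set the blood-pressure network needs —
1-D convolution, batch normalization, ReLU, max pooling, global average
pooling, and fully-connected layers — with hand-derived backward passes and
an Adam optimizer. Convolutions use an im2col formulation
(``sliding_window_view`` + ``einsum``) and "same"-style zero padding, so the
output length is ``ceil(L / stride)``.

All layers expose ``forward(x, training)``, ``backward(grad)``, and
``params()`` returning :class:`Param` objects that pair a value with its
accumulated gradient.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "Flatten",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad", "name", "is_weight")

    def __init__(self, value: np.ndarray, name: str = "", is_weight: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        # is_weight marks convolution/FC weight matrices: the only tensors
        # the L2 penalty applies to (biases and batch-norm affine params are
        # exempt)
        self.is_weight = is_weight


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with same-style zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.w = Param(
            _kaiming(rng, (out_channels, in_channels, kernel_size), fan_in),
            name=f"conv{kernel_size}x{out_channels}.w",
            is_weight=True,
        )
        self.b = Param(np.zeros(out_channels), name=f"conv{kernel_size}x{out_channels}.b")
        self.stride = stride
        self.kernel_size = kernel_size

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        k, s = self.kernel_size, self.stride
        out_len = -(-length // s)  # ceil
        total_pad = max((out_len - 1) * s + k - length, 0)
        pl = total_pad // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, total_pad - pl)))
        cols = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (n, c, out, k)
        self._cache = (cols, xp.shape, pl, length)
        return np.einsum("ncok,fck->nfo", cols, self.w.value, optimize=True) + self.b.value[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, pl, length = self._cache
        self.w.grad += np.einsum("nfo,ncok->fck", grad, cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dcols = np.einsum("nfo,fck->ncok", grad, self.w.value, optimize=True)
        dxp = np.zeros(xp_shape)
        out = grad.shape[2]
        s = self.stride
        for t in range(self.kernel_size):
            dxp[:, :, t : t + out * s : s] += dcols[:, :, :, t]
        return dxp[:, :, pl : pl + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time) with affine params."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), name="bn.gamma")
        self.beta = Param(np.zeros(channels), name="bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        m = shape[0] * shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[:, None]
        # standard batch-norm gradient through the batch statistics
        return (
            inv_std[:, None]
            / m
            * (m * g - g.sum(axis=(0, 2), keepdims=True) - xhat * (g * xhat).sum(axis=(0, 2), keepdims=True))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel = stride); trailing remainder dropped."""

    def __init__(self, kernel_size: int):
        self.k = kernel_size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, length = x.shape
        out = length // self.k
        xr = x[:, :, : out * self.k].reshape(n, c, out, self.k)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        out = grad.shape[2]
        dxr = np.zeros((n, c, out, self.k))
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, length))
        dx[:, :, : out * self.k] = dxr.reshape(n, c, out * self.k)
        return dx


class GlobalAvgPool1d(Layer):
    """Adaptive average pooling to temporal length 1; output is (n, channels)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(
            _kaiming(rng, (in_features, out_features), in_features),
            name=f"fc{out_features}.w",
            is_weight=True,
        )
        self.b = Param(np.zeros(out_features), name=f"fc{out_features}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the conventional moment coefficients (0.9, 0.999, eps 1e-8)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
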