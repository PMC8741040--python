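"""Minimal convolutional-network engine on NumPy.

This is a small, self-contained CNN engine: NHWC tensors, im2col convolutions
lowered to BLAS matrix products, reverse-mode gradients written by hand, and
an Adam optimizer. It exists to power the 21-layer encoder; it is not a
general autograd system. Numerical gradients verify every layer's backward
pass in the test suite.

Conventions
-----------
* activations are ``(N, H, W, C)`` (or ``(N, F)`` after ``Flatten``);
* convolutions use TensorFlow-style "same" padding: ``out = ceil(in/stride)``;
* weights default to float32 for speed; ``Sequential.cast`` switches dtype
  (the gradient checks run in float64).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ArgumentError, ShapeError


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: float = 0.0):
        self.value = value
        self.grad = np.zeros_like(value)
        self.l2 = l2


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for "same" padding."""
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution with bias, "same" padding and optional stride."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, l2: float = 0.0,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        scale = math.sqrt(2.0 / fan_in)  # He initialisation for ReLU-family
        self.kernel = kernel
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels
        w = rng.normal(0.0, scale, size=(kernel, kernel, in_channels, out_channels))
        self.weight = Param(w.astype(dtype), l2=l2)
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ShapeError(
                f"Conv2D expected (N, H, W, {self.in_channels}), got {x.shape}")
        n, h, w, c = x.shape
        k, s = self.kernel, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        windows = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # (N, oh, ow, C, k, k) -> (N*oh*ow, k*k*C)
        cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * oh * ow, k * k * c)
        w_flat = self.weight.value.reshape(k * k * c, self.out_channels)
        out = cols @ w_flat + self.bias.value
        self._cache = (cols, (n, h, w, c), (oh, ow), (pt, pl))
        return out.reshape(n, oh, ow, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c), (oh, ow), (pt, pl) = self._cache
        k, s = self.kernel, self.stride
        gflat = grad.reshape(n * oh * ow, self.out_channels)
        w_flat = self.weight.value.reshape(k * k * c, self.out_channels)
        dw = cols.T @ gflat
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.weight.l2:
            self.weight.grad += self.weight.l2 * self.weight.value
        self.bias.grad += gflat.sum(axis=0)
        dcols = (gflat @ w_flat.T).reshape(n, oh, ow, k, k, c)
        _, _, pbh = _same_pad(h, k, s)
        _, _, pbw = _same_pad(w, k, s)
        dxp = np.zeros((n, h + pt + pbh, w + pl + pbw, c), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        if slope <= 0:
            raise ArgumentError("leaky slope must be > 0")
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not (0.0 <= rate < 1.0):
            raise ArgumentError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, l2: float = 0.0,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = math.sqrt(2.0 / in_features)
        self.weight = Param(
            rng.normal(0.0, scale, size=(in_features, out_features)).astype(dtype),
            l2=l2)
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        if self.weight.l2:
            self.weight.grad += self.weight.l2 * self.weight.value
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class Parallel(Layer):
    """Two branches applied to the same input, concatenated along channels."""

    def __init__(self, left: list[Layer], right: list[Layer]):
        self.left = Sequential(left)
        self.right = Sequential(right)
        self._split = None

    def params(self) -> list[Param]:
        return self.left.params() + self.right.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        lo = self.left.forward(x, train)
        ro = self.right.forward(x, train)
        self._split = lo.shape[-1]
        return np.concatenate([lo, ro], axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gl = self.left.backward(grad[..., :self._split])
        gr = self.right.backward(grad[..., self._split:])
        return gl + gr


class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def cast(self, dtype) -> "Sequential":
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = np.zeros_like(p.value)
        return self

    def walk(self):
        """Depth-first iteration over all primitive layers."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.walk()
            elif isinstance(layer, Parallel):
                yield layer
                yield from layer.left.walk()
                yield from layer.right.walk()
            else:
                yield layer


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


def l2_penalty(params: list[Param]) -> float:
    """Current value of the L2 regularisation term (for loss reporting)."""
    return float(sum(0.5 * p.l2 * np.sum(p.value.astype(np.float64) ** 2)
                     for p in params if p.l2))
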