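"""Minimal NumPy neural-network core for 1-D convolutional regression.

Implements exactly the layer set the BP extractor needs — 1-D convolution
with "same" padding and ceil(L/stride) output length, batch normalization,
ReLU, sigmoid, inverted dropout, max pooling, global average pooling and
fully connected layers — each with a hand-derived backward pass, plus an
Adam optimizer with optional L2 weight penalty.

Layout convention: activations are (batch, channels, length) float32 arrays;
fully connected activations are (batch, features).  Layers cache what their
backward pass needs on ``self``; a layer instance therefore serves one
forward/backward pair at a time (single-threaded training).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool1d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "same_pad",
    "conv_out_len",
]

F32 = np.float32


def conv_out_len(length: int, stride: int) -> int:
    """Output length of a "same"-padded conv/pool: ceil(L / stride)."""
    return -(-length // stride)


def same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    """Left/right padding so that the output length is ceil(L / stride)."""
    out = conv_out_len(length, stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in the L2 penalty (weights, not biases)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation), "same" padding, stride >= 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out), decay=False)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, c, length = x.shape
        pl, pr = same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        lo = win.shape[2]
        # (n, lo, c*k) matrix so the contraction is one GEMM
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, lo, c * self.kernel)
        wm = self.w.value.reshape(self.c_out, -1)
        y = cols @ wm.T + self.b.value
        self._cache = (cols, (n, c, length, pl, lo))
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        cols, (n, c, length, pl, lo) = self._cache
        k, s = self.kernel, self.stride
        g = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (n, lo, c_out)
        gm = g.reshape(n * lo, self.c_out)
        self.w.grad += (gm.T @ cols.reshape(n * lo, c * k)).reshape(self.w.value.shape)
        self.b.grad += gm.sum(axis=0)
        dcols = (gm @ self.w.value.reshape(self.c_out, -1)).reshape(n, lo, c, k)
        pr_len = pl + length
        padded_len = max((lo - 1) * s + k, length + pl)
        dxp = np.zeros((n, c, padded_len), dtype=F32)
        for j in range(k):
            dxp[:, :, j : j + s * lo : s] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pl:pr_len]


class BatchNorm1d(Layer):
    """Batch normalization over (batch, length) per channel; running
    statistics are used at inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, v):
        return v.reshape(1, -1, 1)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean.astype(F32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(F32) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv)
        if train:
            self._cache = (xhat, inv)
        return (self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)).astype(F32)

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self._shape(self.gamma.value * inv.astype(F32))
        mean_dy = dy.mean(axis=(0, 2))
        mean_dy_xhat = (dy * xhat).sum(axis=(0, 2)) / m
        dx = g * (dy - self._shape(mean_dy) - xhat * self._shape(mean_dy_xhat))
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(F32)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(F32)

    def backward(self, dy):
        return (dy * self._y * (1.0 - self._y)).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1d(Layer):
    """Max pooling with "same" padding (stride 1 keeps the length)."""

    def __init__(self, kernel: int, stride: int = 1):
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train):
        n, c, length = x.shape
        pl, pr = same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        arg = win.argmax(axis=3)
        y = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        lo = y.shape[2]
        starts = np.arange(lo) * self.stride
        self._cache = (arg + starts, (n, c, length, pl, xp.shape[2]))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        pos, (n, c, length, pl, plen) = self._cache
        dxp = np.zeros((n, c, plen), dtype=F32)
        flat = (
            np.arange(n)[:, None, None] * (c * plen)
            + np.arange(c)[None, :, None] * plen
            + pos
        )
        np.add.at(dxp.reshape(-1), flat.ravel(), dy.ravel())
        return dxp[:, :, pl : pl + length]


class GlobalAvgPool(Layer):
    """(n, c, l) -> (n, c) average over the temporal axis."""

    def forward(self, x, train):
        self._l = x.shape[2]
        return x.mean(axis=2).astype(F32)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._l, self._l, axis=2).astype(F32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_out, d_in)))
        self.b = Param(np.zeros(d_out), decay=False)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with coupled L2 penalty on weight (decay=True) parameters."""

    def __init__(self, params: list[Param], lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + 2.0 * self.l2 * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
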