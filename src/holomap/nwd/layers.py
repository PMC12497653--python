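"""Minimal 1-D neural-network layers (NumPy, explicit backprop).

Shapes are (batch, channels, length) throughout.  Each layer caches what its
backward pass needs; parameters and gradients are exposed as lists so an
optimizer can walk the whole model.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padding 1-D convolution, stride 1, odd kernel size.

    A transposed (fractionally strided) convolution with stride 1 is the
    adjoint of this map and spans the same operator class, so the expansion
    path reuses this layer for its transposed convolutions.
    """

    def __init__(self, c_in, c_out, kernel, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=True):
        b, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # convolution as a sum of channel-mixing matmuls over kernel taps:
        # cheaper than materializing an im2col matrix for small kernels
        y = np.zeros((b, self.c_out, length), dtype=x.dtype)
        for j in range(self.k):
            y += np.matmul(self.w[:, :, j], xp[:, :, j : j + length])
        y += self.b[None, :, None]
        if train:
            self._xp = xp
        return y

    def backward(self, dy):
        b, _, length = dy.shape
        p = self.k // 2
        xp = self._xp
        self.db[...] = dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            self.dw[:, :, j] = np.einsum("bol,bcl->oc", dy, xp[:, :, j : j + length])
            dxp[:, :, j : j + length] += np.matmul(self.w[:, :, j].T, dy)
        self._xp = None
        return dxp[:, :, p : p + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        ) * inv[None, :, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        return np.maximum(x, 0.0)

    def backward(self, dy):
        dx = np.where(self._mask, dy, 0.0)
        self._mask = None
        return dx


class Decimate2(Layer):
    """2x temporal decimation (keep even samples)."""

    def __init__(self):
        self._len = None

    def forward(self, x, train=True):
        self._len = x.shape[2]
        return x[:, :, ::2]

    def backward(self, dy):
        dx = np.zeros(dy.shape[:2] + (self._len,))
        dx[:, :, ::2] = dy
        return dx


class UpsampleLinear2(Layer):
    """2x upsampling by linear interpolation between neighbours."""

    def forward(self, x, train=True):
        b, c, length = x.shape
        out = np.empty((b, c, 2 * length))
        out[:, :, 0::2] = x
        out[:, :, 1:-1:2] = 0.5 * (x[:, :, :-1] + x[:, :, 1:])
        out[:, :, -1] = x[:, :, -1]
        return out

    def backward(self, dy):
        dx = dy[:, :, 0::2].copy()
        mid = dy[:, :, 1:-1:2]
        dx[:, :, :-1] += 0.5 * mid
        dx[:, :, 1:] += 0.5 * mid
        dx[:, :, -1] += dy[:, :, -1]
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, grads, lr=0.01, momentum=0.9):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
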