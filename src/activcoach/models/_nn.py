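"""Minimal 1-D convolutional network primitives (numpy).

Forward/backward passes for the layers the step forecaster needs —
1-D convolution, ReLU, 1-D max pooling, flatten, dense — plus an Adam
optimizer and an MSE loss.  Shapes follow the (batch, time, channels)
convention.  Gradients are exact (verified against numerical differentiation
in the test suite).
"""

from __future__ import annotations

import numpy as np


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows along axis 1: (B, T, C) -> (B, T-k+1, k, C)."""
    B, T, C = x.shape
    out = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    # sliding_window_view yields (B, T-k+1, C, k); put k before C
    return np.ascontiguousarray(np.moveaxis(out, -1, 2))


class Conv1D:
    """Valid (no padding), stride-1 1-D convolution with optional ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, relu: bool = True):
        fan_in = kernel_size * in_channels
        # He initialisation suits the ReLU nonlinearity
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel_size, in_channels, filters))
        self.b = np.zeros(filters)
        self.relu = relu
        self.k = kernel_size

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _windows(x, self.k)                  # (B, T', k, C)
        z = np.einsum("btkc,kcf->btf", self._win, self.W) + self.b
        self._mask = z > 0 if self.relu else None
        self._in_shape = x.shape
        return np.where(self._mask, z, 0.0) if self.relu else z

    def backward(self, grad: np.ndarray):
        if self.relu:
            grad = grad * self._mask
        gW = np.einsum("btkc,btf->kcf", self._win, grad)
        gb = grad.sum(axis=(0, 1))
        B, T, C = self._in_shape
        gx = np.zeros((B, T, C))
        # scatter each window position's contribution back onto the input
        for t in range(grad.shape[1]):
            gx[:, t:t + self.k, :] += np.einsum("bf,kcf->bkc", grad[:, t, :],
                                                self.W)
        return gx, [gW, gb]


class MaxPool1D:
    """Non-overlapping max pooling (pool size = stride), valid mode."""

    def __init__(self, pool_size: int = 2):
        self.p = pool_size

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        n = T // self.p
        self._in_shape = x.shape
        blocks = x[:, :n * self.p, :].reshape(B, n, self.p, C)
        self._argmax = blocks.argmax(axis=2)             # (B, n, C)
        return blocks.max(axis=2)

    def backward(self, grad: np.ndarray):
        B, T, C = self._in_shape
        n = grad.shape[1]
        gx = np.zeros((B, n, self.p, C))
        b_idx, n_idx, c_idx = np.ogrid[:B, :n, :C]
        gx[b_idx, n_idx, self._argmax, c_idx] = grad
        out = np.zeros(self._in_shape)
        out[:, :n * self.p, :] = gx.reshape(B, n * self.p, C)
        return out, []


class Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray):
        return grad.reshape(self._in_shape), []


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray):
        gW = self._x.T @ grad
        gb = grad.sum(axis=0)
        return grad @ self.W.T, [gW, gb]


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray):
        grads = []
        for layer in reversed(self.layers):
            grad, layer_grads = layer.backward(grad)
            grads = layer_grads + grads
        return grads


class Adam:
    """Adam with the standard configuration (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
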