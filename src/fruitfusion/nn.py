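"""Minimal convolutional-network building blocks in NumPy.

The detector in this package is deliberately small — a handful of strided
convolutions and one anchor head — so the full forward/backward pass is
written directly against NumPy: convolution as an im2col matrix product,
explicit gradients, and SGD with momentum.  Everything runs in float32 on
one CPU core at the problem sizes this pipeline targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "LeakyReLU", "Sequential", "SGD", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "buf", "is_bias")

    def __init__(self, value: np.ndarray, is_bias: bool = False):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.buf = np.zeros_like(self.value)
        self.is_bias = is_bias


class Conv2d:
    """2D convolution (cross-correlation) with stride and zero padding.

    Weights are He-initialized.  Input/output layout is (N, C, H, W).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (c_out, c_in, kernel, kernel))
        self.weight = Param(w.astype(np.float32))
        self.bias = Param(np.zeros(c_out, dtype=np.float32), is_bias=True)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.weight.value.size + self.bias.value.size

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if x.shape[1] != self.c_in:
            raise ValueError(
                f"layer expects {self.c_in} input channels, got {x.shape[1]}")
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N*Ho*Wo, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wmat = self.weight.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.bias.value
        out = out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, hp, wp = x_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        wmat = self.weight.value.reshape(self.c_out, -1)
        self.weight.grad += (dflat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dflat.sum(axis=0)
        dcols = (dflat @ wmat).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, k, k, Ho, Wo)
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        out = np.where(mask, x, self.slope * x)
        if train:
            self._mask = mask
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class SGD:
    """Stochastic gradient descent with momentum and decoupled bias group.

    Weight decay (L2) applies to weights only.  Learning rate, bias
    learning rate, and momentum are supplied per step so the training loop
    can drive warm-up and decay schedules.
    """

    def __init__(self, params, weight_decay: float = 0.0):
        self.params = list(params)
        self.weight_decay = weight_decay

    def step(self, lr: float, momentum: float,
             bias_lr: float | None = None) -> None:
        bias_lr = lr if bias_lr is None else bias_lr
        for p in self.params:
            g = p.grad
            if not p.is_bias and self.weight_decay:
                g = g + self.weight_decay * p.value
            p.buf *= momentum
            p.buf += g
            p.value -= (bias_lr if p.is_bias else lr) * p.buf
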