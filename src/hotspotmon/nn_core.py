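"""Minimal trainable CNN primitives (NumPy, NCHW layout).

Implements exactly what the hotspot detector needs: stride-1 zero-padded
convolutions, stride-1 unpadded transposed convolutions (output grows by
kernel-1), nearest-neighbor x2 upsampling, batch normalization, ReLU and
sigmoid.  Forward passes cache what their backward passes need; gradients
are accumulated into per-parameter ``grads`` dicts and are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "TransposedConv2D",
    "Upsample2x",
    "BatchNorm2D",
    "ReLU",
    "Sigmoid",
]


def _conv2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation: x (N,C,H,W), w (F,C,k,k) -> (N,F,H',W')."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, w.shape[-2:], axis=(2, 3))
    return np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)


def _conv2d_grads(x, w, pad, dy):
    """Gradients of ``_conv2d`` w.r.t. x and w."""
    k = w.shape[-1]
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    dw = np.einsum("nchwij,nfhw->fcij", win, dy, optimize=True)
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,k,k)
    dxp = _conv2d(dy, w_flip, pad=k - 1)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(dxp), dw


class Layer:
    """Base: parameters live in ``params``; gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_size(self, s: int) -> int:
        return s


class Conv2D(Layer):
    """Zero-padded stride-1 convolution; preserves spatial size (odd kernel)."""

    def __init__(self, c_in, c_out, kernel, rng, dtype=np.float32, bias=True):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("size-preserving convolution needs an odd kernel")
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params["w"] = (scale * rng.standard_normal((c_out, c_in, kernel, kernel))).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x, train):
        self._x = x
        y = _conv2d(x, self.params["w"], self.pad)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy):
        dx, dw = _conv2d_grads(self._x, self.params["w"], self.pad, dy)
        self.grads["w"] = dw
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return dx


class TransposedConv2D(Layer):
    """Stride-1 transposed convolution with no padding: size s -> s + k - 1."""

    def __init__(self, c_in, c_out, kernel, rng, dtype=np.float32, bias=True):
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        # stored as (C_in, C_out, k, k), torch ConvTranspose2d convention
        self.params["w"] = (scale * rng.standard_normal((c_in, c_out, kernel, kernel))).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x, train):
        self._x = x
        w = self.params["w"]
        w_eq = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_out, C_in, k, k)
        y = _conv2d(x, w_eq, pad=self.kernel - 1)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy):
        # forward was a full correlation with the flipped kernel; its adjoint
        # is a valid correlation with the unflipped kernel.
        w = self.params["w"]
        win = sliding_window_view(dy, (self.kernel, self.kernel), axis=(2, 3))
        dx = np.einsum("nfhwij,cfij->nchw", win, w, optimize=True)
        xw = sliding_window_view(
            np.pad(self._x, ((0, 0), (0, 0), (self.kernel - 1,) * 2, (self.kernel - 1,) * 2)),
            dy.shape[-2:],
            axis=(2, 3),
        )
        # xw: (N, C_in, k, k, Ho, Wo); contract with dy over batch and space
        dw_eq = np.einsum("ncijpq,nfpq->fcij", xw, dy, optimize=True)
        self.grads["w"] = dw_eq[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(dx)

    def out_size(self, s):
        return s + self.kernel - 1


class Upsample2x(Layer):
    """Nearest-neighbor doubling of both spatial dimensions."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def out_size(self, s):
        return 2 * s


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, dtype=np.float32, eps=1e-5, momentum=0.9):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._invstd[None, :, None, None]
        return (
            self.params["gamma"][None, :, None, None] * self._xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        g = self.params["gamma"][None, :, None, None]
        s1 = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g * invstd[None, :, None, None] / m) * (m * dy - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self.probs = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self.probs

    def backward(self, dy):
        return dy * self.probs * (1.0 - self.probs)
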