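"""Conv / norm / pool / resize layers with hand-derived backward passes.

Convolution is computed as a sum over the K*K kernel taps, each tap a
single (C_out x C_in) x (C_in x B*H*W) matrix product on a strided view.
This keeps memory flat (no im2col buffer) while doing all heavy lifting
in BLAS, and makes dilation free: a tap at offset (i, j) simply reads the
input shifted by (i*rate, j*rate) — the "insert zeros between taps" view
of atrous convolution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Param

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "UpsampleBilinear2x",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    """2-D cross-correlation with optional stride and dilation (atrous rate).

    Output size follows the usual formula
    ``H_out = (H + 2*padding - dilation*(K-1) - 1) // stride + 1``;
    ``padding=None`` selects "same" padding ``dilation*(K-1)//2`` (exact
    for odd K at stride 1).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, dilation: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        if kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
        if kernel_size % 2 == 0:
            # even kernels break the centered-tap arithmetic used throughout
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.dilation = dilation
        self.kernel_size = kernel_size
        self.padding = dilation * (kernel_size - 1) // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._cache = None

    def _out_hw(self, H: int, W: int) -> tuple[int, int]:
        k, s, d, p = self.kernel_size, self.stride, self.dilation, self.padding
        return ((H + 2 * p - d * (k - 1) - 1) // s + 1,
                (W + 2 * p - d * (k - 1) - 1) // s + 1)

    def _tap_view(self, xp: np.ndarray, i: int, j: int, Ho: int, Wo: int) -> np.ndarray:
        s, d = self.stride, self.dilation
        return xp[:, :, i * d: i * d + (Ho - 1) * s + 1: s,
                  j * d: j * d + (Wo - 1) * s + 1: s]

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        k, p = self.kernel_size, self.padding
        Ho, Wo = self._out_hw(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        W_ = self.weight.value
        y = np.zeros((W_.shape[0], B, Ho, Wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xs = self._tap_view(xp, i, j, Ho, Wo)
                y += np.tensordot(W_[:, :, i, j], xs, axes=([1], [1]))
        y = np.ascontiguousarray(y.transpose(1, 0, 2, 3))
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        if training:
            self._cache = (xp, x.shape, (Ho, Wo))
        return y

    def backward(self, dy):
        xp, x_shape, (Ho, Wo) = self._cache
        B, C, H, W = x_shape
        k, p = self.kernel_size, self.padding
        W_ = self.weight.value
        dyT = np.ascontiguousarray(dy.transpose(1, 0, 2, 3))  # (Cout,B,Ho,Wo)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = self._tap_view(xp, i, j, Ho, Wo)
                self.weight.grad[:, :, i, j] += np.tensordot(
                    dyT, xs, axes=([1, 2, 3], [0, 2, 3]))
                t = np.tensordot(W_[:, :, i, j], dyT, axes=([0], [0]))  # (Cin,B,Ho,Wo)
                self._tap_view(dxp, i, j, Ho, Wo)[...] += t.transpose(1, 0, 2, 3)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._cache = None
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if training:
            self._cache = (xhat.astype(np.float32), std)
        return y.astype(np.float32)

    def backward(self, dy):
        xhat, std = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        g = self.gamma.value[None, :, None, None]
        mean_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None] / n
        mean_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / n
        dx = (g / std[None, :, None, None]) * (dy - mean_dy - xhat * mean_dy_xhat)
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    """k x k max pooling; used only for the ResNet stem (3x3, stride 2)."""

    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x, training=False):
        k, s, p = self.kernel_size, self.stride, self.padding
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        B, C, Ho, Wo = win.shape[:4]
        flat = win.reshape(B, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape, xp.shape[2:], (Ho, Wo))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, x_shape, (Hp, Wp), (Ho, Wo) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        B, C, H, W = x_shape
        rows = (np.arange(Ho) * s)[None, None, :, None] + idx // k
        cols = (np.arange(Wo) * s)[None, None, None, :] + idx % k
        pos = (rows * Wp + cols).reshape(B * C, -1)
        dxp = np.zeros((B * C, Hp * Wp), dtype=np.float32)
        bc = np.repeat(np.arange(B * C), Ho * Wo)
        np.add.at(dxp, (bc, pos.ravel()), dy.reshape(B * C, -1).ravel())
        dxp = dxp.reshape(B, C, Hp, Wp)
        self._cache = None
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


def _linear_upsample_matrix(n_in: int) -> np.ndarray:
    """(2n x n) interpolation matrix for exact 2x linear resize.

    Sample positions follow the half-pixel convention
    src = (i_out + 0.5)/2 - 0.5 with edge clamping.
    """
    n_out = 2 * n_in
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    A = np.zeros((n_out, n_in), dtype=np.float32)
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    np.add.at(A, (np.arange(n_out), lo), (1.0 - frac).astype(np.float32))
    np.add.at(A, (np.arange(n_out), hi), frac.astype(np.float32))
    return A


class UpsampleBilinear2x(Module):
    """Separable bilinear 2x upsampling; backward is the exact adjoint."""

    _matrices: dict[int, np.ndarray] = {}

    def __init__(self):
        self._in_hw = None

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._matrices:
            cls._matrices[n] = _linear_upsample_matrix(n)
        return cls._matrices[n]

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        Ah, Aw = self._mat(H), self._mat(W)
        y = np.einsum("oh,bchw->bcow", Ah, x, optimize=True)
        y = np.einsum("pw,bcow->bcop", Aw, y, optimize=True)
        if training:
            self._in_hw = (H, W)
        return np.ascontiguousarray(y.astype(np.float32))

    def backward(self, dy):
        H, W = self._in_hw
        Ah, Aw = self._mat(H), self._mat(W)
        dx = np.einsum("pw,bcop->bcow", Aw, dy, optimize=True)
        dx = np.einsum("oh,bcow->bchw", Ah, dx, optimize=True)
        self._in_hw = None
        return np.ascontiguousarray(dx.astype(np.float32))
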