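"""Minimal 3D convolutional network engine in numpy.

Implements exactly the layers the segmentation architecture needs —
3D convolution (stride 1, "same" padding), batch normalization, ReLU,
2x2x2 max pooling, trilinear 2x upsampling — each with a hand-derived
backward pass, plus the Adam optimizer.  Tensors are channel-first:
``(C, D, H, W)`` for a single volume (full-volume training uses one
volume per step).

Convolutions use an im2col layout so both the forward pass and the two
weight/input gradients reduce to BLAS matrix products; the input
gradient of a stride-1 convolution is itself a stride-1 convolution
with spatially flipped, channel-transposed kernels, so no col2im
scatter is needed.

Everything is float32 and deterministic given the initialization seed.
All backward passes are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool2",
    "TrilinearUp2",
    "Adam",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) patch matrix with 'same' zero padding."""
    c = x.shape[0]
    p = (k - 1) // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    # (C, D, H, W, k, k, k) -> (D, H, W, C, k, k, k) -> (N, C*k^3)
    n = win.shape[1] * win.shape[2] * win.shape[3]
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(n, c * k**3)


class Conv3d:
    """Stride-1 3D convolution with cubic kernel and 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k**3
        # He initialization, appropriate for ReLU-activated stacks
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k, k, k)))
        self.b = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, d, h, w = x.shape
        cols = _im2col(x, self.k)
        wmat = self.w.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b.value
        if training:
            self._cols, self._shape = cols, (c, d, h, w)
        else:
            self._cols = None
        return np.ascontiguousarray(y.T.reshape(self.out_ch, d, h, w))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        gmat = gy.reshape(self.out_ch, -1).T  # (N, out_ch)
        self.b.grad += gmat.sum(axis=0)
        self.w.grad += (gmat.T @ self._cols).reshape(self.w.value.shape)
        self._cols = None
        # dx = conv(gy, flipped kernels with channels transposed)
        wt = self.w.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        cols_g = _im2col(np.ascontiguousarray(gy), self.k)
        wmat_t = np.ascontiguousarray(wt).reshape(self.in_ch, -1)
        gx = cols_g @ wmat_t.T
        return np.ascontiguousarray(gx.T.reshape(c, d, h, w))


class BatchNorm3d:
    """Per-channel batch normalization over all spatial voxels.

    Training mode normalizes with the current volume's statistics and
    updates running estimates (momentum 0.1); evaluation mode uses the
    running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if training:
            mean = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean[:, None]) * inv_std[:, None]
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        if training:
            self._cache = (xhat, inv_std)
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        c = gy.shape[0]
        g = gy.reshape(c, -1)
        n = g.shape[1]
        self.gamma.grad += (g * xhat).sum(axis=1)
        self.beta.grad += g.sum(axis=1)
        coef = self.gamma.value[:, None] * inv_std[:, None] / n
        gx = coef * (
            n * g - g.sum(axis=1, keepdims=True) - xhat * (g * xhat).sum(axis=1, keepdims=True)
        )
        return gx.reshape(gy.shape).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool2:
    """2x2x2 max pooling with stride 2.  Spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, d, h, w = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        xw = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (c, d, h, w))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (c, d, h, w) = self._cache
        self._cache = None
        gwin = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gwin, idx[..., None], gy[..., None], axis=-1)
        gx = gwin.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return np.ascontiguousarray(gx.reshape(c, d, h, w))


def _interp_matrix(n: int) -> np.ndarray:
    """(2n, n) linear-interpolation matrix for 2x upsampling.

    Cell-centered (align_corners off): output sample o reads source
    coordinate o/2 - 0.25, clamped at the edges.
    """
    a = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        src = o / 2.0 - 0.25
        src = min(max(src, 0.0), n - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n - 1)
        w = src - i0
        a[o, i0] += 1.0 - w
        a[o, i1] += w
    return a


class TrilinearUp2:
    """Trilinear 2x upsampling along all three spatial axes."""

    _matrices: dict[int, np.ndarray] = {}

    def __init__(self):
        self._shape = None

    def parameters(self) -> list[Param]:
        return []

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._matrices:
            cls._matrices[n] = _interp_matrix(n)
        return cls._matrices[n]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, d, h, w = x.shape
        if training:
            self._shape = (c, d, h, w)
        y = np.tensordot(self._mat(d), x, axes=(1, 1))  # (2d, C, H, W)
        y = np.tensordot(self._mat(h), y, axes=(1, 2))  # (2h, 2d, C, W)
        y = np.tensordot(self._mat(w), y, axes=(1, 3))  # (2w, 2h, 2d, C)
        return np.ascontiguousarray(y.transpose(3, 2, 1, 0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        self._shape = None
        g = np.tensordot(self._mat(d).T, gy, axes=(1, 1))  # (d, C, 2H, 2W)
        g = np.tensordot(self._mat(h).T, g, axes=(1, 2))  # (h, d, C, 2W)
        g = np.tensordot(self._mat(w).T, g, axes=(1, 3))  # (w, h, d, C)
        return np.ascontiguousarray(g.transpose(3, 2, 1, 0))


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
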