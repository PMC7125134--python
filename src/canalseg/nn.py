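"""Minimal 3D convolutional network layers with explicit backprop.

Implements exactly the operations the segmentation network needs — 3x3x3
and 1x1x1 convolutions (stride 1 or 2), stride-2 transpose convolutions,
batch normalisation, ReLU — plus the Adam optimiser. Activations are kept
channels-last ``(batch, x, y, z, channels)`` float32 throughout; every
convolution pass (forward, input gradient, weight gradient) is phrased as a
patch-matrix extraction (im2col, a tight copy loop compiled with numba)
followed by one large matrix product, which keeps the arithmetic in BLAS.
The input gradient of a strided convolution is computed as a stride-1
convolution of the zero-stuffed upstream gradient with the flipped kernel.

Each layer caches what its backward pass needs during a training-mode
forward; ``backward`` consumes the upstream gradient, accumulates parameter
gradients in-place, and returns the input gradient.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Large activation buffers are allocated and freed every layer call; glibc
# would hand them back to the kernel each time (mmap/munmap), making every
# reuse page-fault. Raising the mmap and trim thresholds keeps these blocks
# on the heap, which speeds training several-fold. Process-global, harmless
# elsewhere; silently skipped off glibc platforms.
try:  # pragma: no cover - platform dependent
    import ctypes

    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    _libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
except Exception:
    pass


@njit(cache=True)
def _im2col(x: np.ndarray, k: int, s: int, p: int, cols: np.ndarray) -> None:
    """Gather zero-padded k^3 neighbourhoods into contiguous rows.

    x: (B, D, H, W, C) unpadded input; cols: (B, Do, Ho, Wo, k^3*C)
    preallocated output. Feature order is (offset-major, channel-minor);
    out-of-range taps read as zero.
    """
    B, D, H, W, C = x.shape
    Do, Ho, Wo = cols.shape[1], cols.shape[2], cols.shape[3]
    for b in range(B):
        for zi in range(Do):
            for yi in range(Ho):
                for xi in range(Wo):
                    dst = cols[b, zi, yi, xi]
                    m = 0
                    for di in range(k):
                        z = zi * s + di - p
                        for dj in range(k):
                            y = yi * s + dj - p
                            ok = 0 <= z < D and 0 <= y < H
                            for dl in range(k):
                                xx = xi * s + dl - p
                                if ok and 0 <= xx < W:
                                    xv = x[b, z, y, xx]
                                    for c in range(C):
                                        dst[m] = xv[c]
                                        m += 1
                                else:
                                    for c in range(C):
                                        dst[m] = 0.0
                                        m += 1


def _cols_of(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """im2col with padding; output spatial size (n + 2p - k) // s + 1."""
    out = tuple((n + 2 * p - k) // s + 1 for n in x.shape[1:4])
    cols = np.empty(
        (x.shape[0],) + out + (k**3 * x.shape[4],), dtype=np.float32
    )
    _im2col(np.ascontiguousarray(x), k, s, p, cols)
    return cols


def _stuff(x: np.ndarray, s: int, extra: int = 0) -> np.ndarray:
    """Zero-stuff spatial axes by stride ``s`` (+ ``extra`` trailing zeros)."""
    if s == 1 and extra == 0:
        return x
    B, D, H, W, C = x.shape
    out = np.zeros(
        (B, s * (D - 1) + 1 + extra, s * (H - 1) + 1 + extra,
         s * (W - 1) + 1 + extra, C),
        dtype=np.float32,
    )
    out[:, 0 : s * (D - 1) + 1 : s,
        0 : s * (H - 1) + 1 : s,
        0 : s * (W - 1) + 1 : s] = x
    return out


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Conv3d:
    """3D convolution, kernel 1 or 3, stride 1 or 2, channels-last."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias_init: float = 0.0,
        needs_input_grad: bool = True,
    ):
        if pad is None:
            pad = kernel // 2
        self.stride = stride
        self.pad = pad
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.needs_input_grad = needs_input_grad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel**3
        self.weight = Parameter(
            rng.standard_normal((out_ch, in_ch, kernel, kernel, kernel))
            * _he_std(fan_in)
        )
        self.bias = Parameter(np.full(out_ch, bias_init, dtype=np.float32))
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def buffers(self) -> list[np.ndarray]:
        return []

    def _w_fwd(self) -> np.ndarray:
        # (k^3 * C, O) in im2col feature order
        return np.ascontiguousarray(
            self.weight.data.transpose(2, 3, 4, 1, 0).reshape(-1, self.out_ch)
        )

    def _w_flip(self) -> np.ndarray:
        # flipped kernel mapping O -> C, for the input gradient
        wf = self.weight.data[:, :, ::-1, ::-1, ::-1]
        return np.ascontiguousarray(
            wf.transpose(2, 3, 4, 0, 1).reshape(-1, self.in_ch)
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if k == 1 and s == 1:
            B = x.shape[0]
            xf = x.reshape(-1, self.in_ch)
            y = xf @ self.weight.data.reshape(self.out_ch, self.in_ch).T
            y += self.bias.data
            if training:
                self._cache = (xf, x.shape)
            return y.reshape(x.shape[:4] + (self.out_ch,))
        cols = _cols_of(x, k, s, p)
        y = cols.reshape(-1, cols.shape[-1]) @ self._w_fwd() + self.bias.data
        if training:
            self._cache = (cols, x.shape)
        return y.reshape(cols.shape[:4] + (self.out_ch,))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        gyf = gy.reshape(-1, self.out_ch)
        self.bias.grad += gyf.sum(axis=0)
        if k == 1 and s == 1:
            xf, x_shape = self._cache
            self.weight.grad += (gyf.T @ xf).reshape(self.weight.data.shape)
            self._cache = None
            if not self.needs_input_grad:
                return None
            gx = gyf @ self.weight.data.reshape(self.out_ch, self.in_ch)
            return gx.reshape(x_shape)
        cols, x_shape = self._cache
        gw = cols.reshape(-1, cols.shape[-1]).T @ gyf  # (k^3*C, O)
        self.weight.grad += gw.reshape(
            (k, k, k, self.in_ch, self.out_ch)
        ).transpose(4, 3, 0, 1, 2)
        if not self.needs_input_grad:
            self._cache = None
            return None
        # input gradient: stride-1 correlation of the zero-stuffed upstream
        # gradient with the flipped kernel, cropped by the forward padding
        gz = _stuff(gy, s)
        gcols = _cols_of(gz, k, 1, k - 1)
        gxpad = gcols.reshape(-1, gcols.shape[-1]) @ self._w_flip()
        gxpad = gxpad.reshape(gcols.shape[:4] + (self.in_ch,))
        B, D, H, W, C = x_shape
        self._cache = None
        if p == 0:
            return gxpad
        return np.ascontiguousarray(
            gxpad[:, p : p + D, p : p + H, p : p + W]
        )


class ConvTranspose3d:
    """Stride-2 3x3x3 transpose convolution doubling each spatial axis."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.stride = stride
        self.pad = pad
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel**3
        self.weight = Parameter(
            rng.standard_normal((in_ch, out_ch, kernel, kernel, kernel))
            * _he_std(fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # equivalent stride-1 correlation of the zero-stuffed input (one
        # trailing zero per axis so each spatial size exactly doubles) with
        # the flipped kernel
        k, s, p = self.kernel, self.stride, self.pad
        xz = _stuff(x, s, extra=1)
        cols = _cols_of(xz, k, 1, k - 1 - p)
        wf = self.weight.data[:, :, ::-1, ::-1, ::-1]
        w2 = np.ascontiguousarray(
            wf.transpose(2, 3, 4, 0, 1).reshape(-1, self.out_ch)
        )
        y = cols.reshape(-1, cols.shape[-1]) @ w2 + self.bias.data
        if training:
            self._cache = (x.reshape(-1, self.in_ch), x.shape)
        return y.reshape(cols.shape[:4] + (self.out_ch,))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xf, x_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        self.bias.grad += gy.reshape(-1, self.out_ch).sum(axis=0)
        gcols = _cols_of(gy, k, s, p)  # (B, D, H, W, k^3*O)
        gcf = gcols.reshape(-1, gcols.shape[-1])
        # weight gradient: correlate cached input with upstream windows
        gw = xf.T @ gcf  # (C, k^3*O)
        self.weight.grad += gw.reshape(
            (self.in_ch, k, k, k, self.out_ch)
        ).transpose(0, 4, 1, 2, 3)
        w2 = np.ascontiguousarray(
            self.weight.data.transpose(2, 3, 4, 1, 0).reshape(-1, self.in_ch)
        )
        gx = gcf @ w2
        self._cache = None
        return gx.reshape(x_shape)


class BatchNorm3d:
    """Per-channel batch normalisation over (batch, x, y, z)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x - mean.astype(np.float32)) * ivar
            self._cache = (xhat, ivar)
        else:
            ivar = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
            xhat = (x - self.running_mean) * ivar
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, 1, 2, 3)
        self.beta.grad += gy.sum(axis=axes)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        gxhat = gy * self.gamma.data
        gx = (
            gxhat
            - gxhat.mean(axis=axes).astype(np.float32)
            - xhat * (gxhat * xhat).mean(axis=axes).astype(np.float32)
        ) * ivar
        self._cache = None
        return gx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
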