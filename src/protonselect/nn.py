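"""Minimal CPU convolutional-network engine used by the dose predictor.

Implements exactly the pieces the encoder–decoder dose-regression model
needs — 2-D convolution (im2col), ReLU, 2×2 max-pooling, fractionally-
strided (transposed) convolution, residual bottleneck blocks and Adam —
with explicit forward/backward passes on numpy arrays. Tensors are NCHW
``float32``. All initialisation is drawn from a caller-supplied generator,
so identical seeds give bit-identical weights and training trajectories on
one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2D", "ConvTranspose2x2", "ReLU", "MaxPool2",
           "Bottleneck", "Adam"]


class Param:
    """A weight tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2D:
    """Same-padded 2-D convolution with stride 1 or 2."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int, stride: int = 1):
        self.k = kernel
        self.s = stride
        self.p = kernel // 2
        fan_in = c_in * kernel * kernel
        self.W = Param(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._win = None
        self._x_shape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.s, ::self.s]
        self._win = win
        self._x_shape = x.shape
        y = np.einsum("nchwuv,ocuv->nohw", win, self.W.value, optimize=True)
        return y + self.b.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("nchwuv,nohw->ocuv", self._win, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        n, _, h, w = self._x_shape
        p, k, s = self.p, self.k, self.s
        hp, wp = h + 2 * p, w + 2 * p
        # scatter dy back onto the stride-1 output grid, then full-correlate
        dyz = np.zeros((dy.shape[0], dy.shape[1], hp - k + 1, wp - k + 1), dtype=dy.dtype)
        dyz[:, :, ::s, ::s] = dy
        dyp = np.pad(dyz, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        w_rot = self.W.value[:, :, ::-1, ::-1]
        win = sliding_window_view(dyp, (k, k), axis=(2, 3))
        dxp = np.einsum("nohwuv,ocuv->nchw", win, w_rot, optimize=True)
        self._win = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2x2:
    """Fractionally-strided convolution: kernel 2, stride 2, doubles H and W."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.W = Param(_he_init(rng, (c_in, c_out, 2, 2), c_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y6 = np.einsum("nchw,couv->nohwuv", x, self.W.value, optimize=True)
        y = y6.transpose(0, 1, 2, 4, 3, 5).reshape(n, y6.shape[1], 2 * h, 2 * w)
        return y + self.b.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, o, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dy6 = dy.reshape(n, o, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        self.W.grad += np.einsum("nchw,nohwuv->couv", self._x, dy6, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohwuv,couv->nchw", dy6, self.W.value, optimize=True)
        self._x = None
        return dx


class ConvTranspose2D:
    """Fractionally-strided convolution with overlapping kernels.

    Kernel 4, stride 2, padding 1 doubles H and W with a smooth overlapping
    reconstruction basis (the standard learned-upsampling choice).
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int = 4, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = kernel, stride, pad
        # each output pixel sees c_in * (k/s)^2 inputs
        fan_in = c_in * (kernel // stride) ** 2
        self.W = Param(_he_init(rng, (c_in, c_out, kernel, kernel), fan_in))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._win = None
        self._dy_pad = None

    def params(self):
        return [self.W, self.b]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (self.s * (h - 1) + self.k - 2 * self.p,
                self.s * (w - 1) + self.k - 2 * self.p)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        xs = np.zeros((n, c, s * (h - 1) + 1, s * (w - 1) + 1), dtype=x.dtype)
        xs[:, :, ::s, ::s] = x
        e = k - 1 - p
        xp = np.pad(xs, ((0, 0), (0, 0), (e, e), (e, e)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self._win = win
        w_rot = self.W.value[:, :, ::-1, ::-1]
        y = np.einsum("nchwuv,couv->nohw", win, w_rot, optimize=True)
        return y + self.b.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        dw_rot = np.einsum("nchwuv,nohw->couv", self._win, dy, optimize=True)
        self.W.grad += dw_rot[:, :, ::-1, ::-1]
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        win = sliding_window_view(dyp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        dx = np.einsum("nohwuv,couv->nchw", win, self.W.value, optimize=True)
        self._win = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2:
    """2×2 max pooling, stride 2; first-index tie-breaking (deterministic)."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = x6.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return dx.reshape(n, c, h, w)


class Bottleneck:
    """Residual bottleneck: 1×1 → 3×3 (optional stride 2) → 1×1 with skip.

    The skip path is the identity when shapes match, otherwise a strided
    1×1 projection.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 stride: int = 1, mid: int | None = None):
        mid = mid if mid is not None else max(c_out // 4, 4)
        self.conv1 = Conv2D(rng, c_in, mid, 1)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(rng, mid, mid, 3, stride=stride)
        self.relu2 = ReLU()
        self.conv3 = Conv2D(rng, mid, c_out, 1)
        self.proj = Conv2D(rng, c_in, c_out, 1, stride=stride) \
            if (stride != 1 or c_in != c_out) else None
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params() + self.conv3.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        h = self.conv3.forward(h)
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(h + skip)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dh = self.conv3.backward(d)
        dh = self.relu2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dx = self.conv1.backward(dh)
        dx_skip = self.proj.backward(d) if self.proj is not None else d
        return dx + dx_skip


class Adam:
    """Adam optimiser over a flat parameter list."""

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
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
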