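"""Trainable layers with explicit forward/backward passes.

Conventions
-----------
* Tensors are ``(N, C, H, W)`` float32 arrays.
* ``forward(x, train=...)`` caches whatever the matching ``backward(dout)``
  needs; ``backward`` returns ``d loss / d input`` and accumulates parameter
  gradients into ``Param.grad``.
* Convolutions use "same" zero padding; pooling/up-convolutions use a fixed
  factor of 2, so spatial sides must be even where pooling is applied.
"""

from __future__ import annotations

import numpy as np

from mammoseg.nn import _conv_kernels as _ck

F32 = np.float32


class Param:
    """A trainable tensor plus its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def size(self) -> int:
        return int(self.value.size)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2d:
    """k×k convolution, stride 1, same padding, via im2col + sgemm."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel size")
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = Param(f"{name}.W", _he_uniform(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=F32))
        self._cols: np.ndarray | None = None
        self._xp: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c * self.k * self.k, h * w), dtype=F32)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, :, di:di + h, dj:dj + w]
                cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, h * w)
                idx += 1
        return cols

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.k == 3 and _ck.HAVE_NUMBA:
            return self._forward_direct(x, train)
        n, c, h, w = x.shape
        cols = self._im2col(x)
        wm = self.W.value.transpose(0, 2, 3, 1).reshape(self.c_out, -1)
        # wm rows are laid out (di, dj, c) to match the im2col ordering
        out = np.matmul(wm, cols) + self.b.value[None, :, None]
        self._cols = cols if train else None
        self._xshape = x.shape
        return out.reshape(n, self.c_out, h, w)

    def _forward_direct(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(np.ascontiguousarray(x, dtype=F32), ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((n, self.c_out, h, w), dtype=F32)
        _ck.conv3x3_forward(xp, self.W.value, out)
        out += self.b.value[None, :, None, None]
        self._xp = xp if train else None
        self._xshape = x.shape
        return out

    def _backward_direct(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dout = np.ascontiguousarray(dout, dtype=F32)
        _ck.conv3x3_wgrad(self._xp, dout, self.W.grad)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dop = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        wt = np.ascontiguousarray(self.W.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx = np.zeros((n, c, h, w), dtype=F32)
        _ck.conv3x3_forward(dop, wt, dx)
        self._xp = None
        return dx

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.k == 3 and _ck.HAVE_NUMBA:
            return self._backward_direct(dout)
        n, c, h, w = self._xshape
        dm = dout.reshape(n, self.c_out, h * w)
        cols = self._cols
        wm = self.W.value.transpose(0, 2, 3, 1).reshape(self.c_out, -1)
        dwm = np.einsum("nop,nqp->oq", dm, cols, optimize=True)
        self.W.grad += dwm.reshape(self.c_out, self.k, self.k, self.c_in).transpose(0, 3, 1, 2)
        self.b.grad += dm.sum(axis=(0, 2))
        dcols = np.matmul(wm.T, dm)  # (n, c*k*k, h*w)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, idx * c:(idx + 1) * c, :].reshape(n, c, h, w)
                idx += 1
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d:
    """2×2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, name: str, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(f"{name}.W", _he_uniform(rng, (c_in, c_out, 2, 2), c_in * 4))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=F32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.empty((n, self.c_out, 2 * h, 2 * w), dtype=F32)
        for i in range(2):
            for j in range(2):
                out[:, :, i::2, j::2] = np.einsum(
                    "nchw,co->nohw", x, self.W.value[:, :, i, j], optimize=True)
        out += self.b.value[None, :, None, None]
        self._x = x if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                sub = dout[:, :, i::2, j::2]
                self.W.grad[:, :, i, j] += np.einsum("nchw,nohw->co", x, sub, optimize=True)
                dx += np.einsum("nohw,co->nchw", sub, self.W.value[:, :, i, j], optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self._x = None
        return dx


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, name: str, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.name = name
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=F32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=F32))
        # running stats are state, not trainable parameters
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat.astype(F32), inv.astype(F32))
        return out.astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(F32)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d:
    """2×2 max pooling, stride 2; backward routes to the argmax position."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial sides, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        del self._idx
        return dx


class Dropout:
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx
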