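"""Minimal CPU neural-network layers with explicit backpropagation.

Tensors are float32 numpy arrays in channels-first layout: ``(N, C, H, W)``
for 2D and ``(N, C, D, H, W)`` for 3D.  Convolutions use the im2col trick so
both passes reduce to BLAS matmuls; the data gradient of a stride-1 padded
convolution is itself a convolution with the spatially flipped, transposed
kernel.  Every layer caches what its backward pass needs; call order must be
forward-then-backward per step.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, *S) -> (N * prod(S), C * k^d) patch matrix for a stride-1,
    pad-(k//2) convolution."""
    d = x.ndim - 2
    pad = k // 2
    xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * d)
    sw = sliding_window_view(xp, (k,) * d, axis=tuple(range(2, 2 + d)))
    # (N, C, *S, *k) -> (N, *S, C, *k)
    sw = np.moveaxis(sw, 1, 1 + d)
    n = x.shape[0]
    spatial = int(np.prod(x.shape[2:]))
    return np.ascontiguousarray(sw).reshape(n * spatial, -1)


class ConvND(Layer):
    """3^d convolution, stride 1, zero padding k//2 (shape preserving)."""

    def __init__(self, in_c: int, out_c: int, dims: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.in_c, self.out_c, self.dims, self.k = in_c, out_c, dims, kernel
        fan_in = in_c * kernel**dims
        self.W = (rng.standard_normal((out_c, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_c, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if train else None
        y = cols @ self.W.T + self.b
        n, spatial = x.shape[0], x.shape[2:]
        y = y.reshape(n, *spatial, self.out_c)
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, spatial = self._shape[0], self._shape[2:]
        dy_flat = np.moveaxis(dy, 1, -1).reshape(-1, self.out_c)
        self.dW += dy_flat.T @ self._cols
        self.db += dy_flat.sum(axis=0)
        # data gradient = convolution of dy with flipped / transposed kernel
        Wk = self.W.reshape(self.out_c, self.in_c, *(self.k,) * self.dims)
        Wk = np.flip(Wk, axis=tuple(range(2, 2 + self.dims)))
        Wt = np.ascontiguousarray(np.swapaxes(Wk, 0, 1)).reshape(self.in_c, -1)
        dyc = _im2col(dy, self.k)
        dx = dyc @ Wt.T
        dx = dx.reshape(n, *spatial, self.in_c)
        self._cols = None
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Conv1x1(Layer):
    """Pointwise convolution: a linear map over channels."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator):
        self.in_c, self.out_c = in_c, out_c
        self.W = (rng.standard_normal((out_c, in_c)) * np.sqrt(2.0 / in_c)).astype(
            np.float32
        )
        self.b = np.zeros(out_c, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return np.moveaxis(np.moveaxis(x, 1, -1) @ self.W.T + self.b, -1, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy_flat = np.moveaxis(dy, 1, -1).reshape(-1, self.out_c)
        x_flat = np.moveaxis(self._x, 1, -1).reshape(-1, self.in_c)
        self.dW += dy_flat.T @ x_flat
        self.db += dy_flat.sum(axis=0)
        dx = dy_flat @ self.W
        dx = dx.reshape(np.moveaxis(self._x, 1, -1).shape)
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    def __init__(self, n_c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_c, dtype=np.float32)
        self.beta = np.zeros(n_c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_c, dtype=np.float32)
        self.running_var = np.ones(n_c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def _cshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        cs = self._cshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(cs)) * inv.reshape(cs)
        if train:
            self._xhat, self._inv, self._axes = xhat, inv, axes
        return self.gamma.reshape(cs) * xhat + self.beta.reshape(cs)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cs = self._cshape(dy)
        axes = self._axes
        m = dy.size / dy.shape[1]
        self.dgamma += (dy * self._xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(cs)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(cs)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(cs)
        ) * self._inv.reshape(cs)
        self._xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool(Layer):
    """2^d max-pooling with stride 2; spatial dims must be even."""

    def __init__(self, dims: int):
        self.dims = dims

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial dims {spatial} must be even for 2x pooling")
        shape = (n, c) + sum(((s // 2, 2) for s in spatial), ())
        xr = x.reshape(shape)
        # bring the window axes last and flatten them
        win_axes = tuple(3 + 2 * i for i in range(self.dims))
        xr = np.moveaxis(xr, win_axes, range(xr.ndim - self.dims, xr.ndim))
        flat = xr.reshape(*xr.shape[: -self.dims], -1)
        idx = flat.argmax(axis=-1)
        self._idx, self._inshape = idx, x.shape
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = 2**self.dims
        flat = np.zeros(dy.shape + (k,), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        n, c = self._inshape[:2]
        spatial = self._inshape[2:]
        xr = flat.reshape(dy.shape + (2,) * self.dims)
        win_axes = tuple(range(xr.ndim - self.dims, xr.ndim))
        dst = tuple(3 + 2 * i for i in range(self.dims))
        xr = np.moveaxis(xr, win_axes, dst)
        return xr.reshape(self._inshape)


class ConvTranspose(Layer):
    """2^d transposed convolution with stride 2 (doubles every spatial dim)."""

    def __init__(self, in_c: int, out_c: int, dims: int, rng: np.random.Generator):
        self.in_c, self.out_c, self.dims = in_c, out_c, dims
        k = 2**dims
        self.W = (rng.standard_normal((in_c, out_c * k)) * np.sqrt(2.0 / in_c)).astype(
            np.float32
        )
        self.b = np.zeros(out_c, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        n = x.shape[0]
        spatial = x.shape[2:]
        d = self.dims
        x_flat = np.moveaxis(x, 1, -1).reshape(-1, self.in_c)
        y = x_flat @ self.W  # (N*S, out_c * 2^d)
        y = y.reshape(n, *spatial, self.out_c, *(2,) * d)
        # (n, s0..s_{d-1}, c, f0..f_{d-1}) -> (n, c, s0, f0, s1, f1, ...)
        perm = [0, 1 + d] + [ax for i in range(d) for ax in (1 + i, 2 + d + i)]
        y = y.transpose(perm)
        out_spatial = tuple(2 * s for s in spatial)
        y = y.reshape(n, self.out_c, *out_spatial)
        return y + self.b.reshape((1, -1) + (1,) * d)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        spatial = self._x.shape[2:]
        d = self.dims
        yr = dy.reshape((n, self.out_c) + sum(((s, 2) for s in spatial), ()))
        # (n, c, s0, f0, s1, f1, ...) -> (n, s0..s_{d-1}, c, f0..f_{d-1})
        perm = [0] + [2 + 2 * i for i in range(d)] + [1] + [3 + 2 * i for i in range(d)]
        yr = yr.transpose(perm)
        dy_flat = np.ascontiguousarray(yr).reshape(-1, self.out_c * 2**d)
        x_flat = np.moveaxis(self._x, 1, -1).reshape(-1, self.in_c)
        self.dW += x_flat.T @ dy_flat
        axes = (0,) + tuple(range(2, dy.ndim))
        self.db += dy.sum(axis=axes)
        dx = dy_flat @ self.W.T
        dx = dx.reshape(n, *spatial, self.in_c)
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]
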