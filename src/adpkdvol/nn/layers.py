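"""Layer primitives with explicit forward/backward passes (NCHW layout).

Convolutions are evaluated as matrix products over im2col patches, which
keeps both passes inside BLAS.  Every layer caches what its backward pass
needs; ``params()`` / ``grads()`` expose flat name->array dicts so the
optimizer can treat the network as a list of tensors.
"""
from __future__ import annotations

import numpy as np

__all__ = ["DTYPE", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "Upsample2"]

#: Working precision; float64 is used by the numerical gradient checks.
DTYPE = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same-padding."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch grads back to the grid."""
    n, c, h, w = shape
    pad = k // 2
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, name: str):
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.k = k
        self.name = name
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache  # type: ignore[misc]
        n, cout, h, w = dout.shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(-1, cout))
        self.dw[...] = (dflat.T @ cols).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = dflat @ self.w.reshape(cout, -1)
        self._cache = None
        return _col2im(dcols, xshape, self.k)

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.w": self.dw, f"{self.name}.b": self.db}


class BatchNorm2d:
    def __init__(self, ch: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=DTYPE)
        self.beta = np.zeros(ch, dtype=DTYPE)
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache  # type: ignore[misc]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.gamma": self.dgamma, f"{self.name}.beta": self.dbeta}

    def state(self) -> dict[str, np.ndarray]:
        return {
            f"{self.name}.running_mean": self.running_mean,
            f"{self.name}.running_var": self.running_var,
        }


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache  # type: ignore[misc]
        n, c, h, w = xshape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
        dx = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)
        self._cache = None
        return dx


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
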