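"""Neural-network layers in NumPy with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and returns
input gradients from ``backward``; parameters expose ``.value``/``.grad`` pairs
consumed by the optimizer. Shapes follow the PyTorch conventions for 1-D
convolution: ``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "Linear",
    "LayerNorm",
    "Embedding",
    "LeakyReLU",
    "MaxPool1d",
    "Dropout",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv1d(Module):
    """Same-padded 1-D convolution with dilation, channels-last.

    Activations are laid out ``(batch, length, channels)``; the im2col matrix
    is materialized from a strided sliding-window view (one cache-friendly
    copy) and cached for the weight-gradient GEMM. The input gradient is
    scattered back with one strided slice-add per kernel tap.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng: np.random.Generator):
        assert kernel % 2 == 1, "same padding requires an odd kernel"
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        self.pad = dilation * (kernel // 2)
        self.w = Param(he_init(rng, (c_in * kernel, c_out), c_in * kernel), "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b")
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, length, c = x.shape
        xp = np.zeros((b, length + 2 * self.pad, c), dtype=DTYPE)
        xp[:, self.pad : self.pad + length, :] = x
        sb, sl, sc = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp,
            shape=(b, length, self.kernel, c),
            strides=(sb, sl, sl * self.dilation, sc),
            writeable=False,
        )
        return win.reshape(b * length, self.kernel * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, length, _ = x.shape
        self._shape = x.shape
        self._cols = self._im2col(x)
        y = self._cols @ self.w.value + self.b.value
        return y.reshape(b, length, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, length, _ = dy.shape
        dy_flat = dy.reshape(b * length, self.c_out)
        self.w.grad += self._cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.w.value.T).reshape(b, length, self.kernel, self.c_in)
        dxp = np.zeros((b, length + 2 * self.pad, self.c_in), dtype=DTYPE)
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, off : off + length, :] += dcols[:, :, k, :]
        self._cols = None
        return dxp[:, self.pad : self.pad + length, :]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(he_init(rng, (d_in, d_out), d_in), "linear.w")
        self.b = Param(np.zeros(d_out), "linear.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim), "ln.gamma")
        self.beta = Param(np.zeros(dim), "ln.beta")
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        self._xhat = self._inv = None
        return dx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0, 1.0, size=(n, dim)), "embed.w")
        self._idx: np.ndarray | None = None

    def forward(self, idx: np.ndarray, train: bool = False) -> np.ndarray:
        self._idx = idx
        return self.w.value[idx]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.w.grad, self._idx, dy)
        self._idx = None
        return None

    def params(self) -> list[Param]:
        return [self.w]


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class MaxPool1d(Module):
    """Non-overlapping max pooling; a trailing remainder of the length is dropped."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, length, c = x.shape
        n_out = length // self.kernel
        self._shape = x.shape
        win = x[:, : n_out * self.kernel, :].reshape(b, n_out, self.kernel, c)
        self._arg = win.argmax(axis=2)
        return win.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, n_out, c = dy.shape
        dwin = np.zeros((b, n_out, self.kernel, c), dtype=DTYPE)
        np.put_along_axis(dwin, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._shape, dtype=DTYPE)
        dx[:, : n_out * self.kernel, :] = dwin.reshape(b, n_out * self.kernel, c)
        self._arg = None
        return dx


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask.astype(DTYPE)
        self._mask = None
        return dx
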