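"""Minimal numpy layers with explicit backward passes.

The package trains small convolutional nets on a single CPU, so the layer set
is deliberately tiny: dense, strided convolution, strided transposed
convolution, elementwise activations and reshapes.  All convolutions use the
im2col/col2im formulation so the heavy lifting is a BLAS matmul.  Arrays are
float32 internally; callers that need tighter guarantees cast on the way out.

Tensor layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "Flatten",
    "Reshape",
    "Sequential",
    "make_activation",
    "sigmoid",
    "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=x.dtype)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, (oh, ow)) with cols of shape (N*oh*ow, C*k*k)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, oh, ow, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * oh * ow, c * k * k), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`.

    ``cols`` has shape (N*oh*ow, C*k*k); returns an array of ``x_shape``.
    """
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols6 = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[
                :, :, :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


class Layer:
    """Base class: stateless by default, parameters in ``params``/``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        std = np.sqrt(gain / n_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Conv2d(Layer):
    """Strided 2-D convolution (default 3x3, stride 2, pad 1 → halves H and W)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
        gain: float = 2.0,
    ):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        std = np.sqrt(gain / fan_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x):
        self._x_shape = x.shape
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        n = x.shape[0]
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        return out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, oh, ow = grad.shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        wmat = self.params["W"].reshape(self.c_out, -1)
        self.grads["W"][...] = (gflat.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"][...] = gflat.sum(axis=0)
        dcols = gflat @ wmat
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Strided transposed convolution (3x3, stride 2, out_pad 1 → doubles H and W).

    Forward is the scatter (col2im) dual of :class:`Conv2d`; backward reuses
    im2col, so both directions are matmul-bound.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
        out_pad: int = 1,
        gain: float = 2.0,
    ):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad, self.out_pad = k, stride, pad, out_pad
        fan_in = c_in * k * k
        std = np.sqrt(gain / fan_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(c_in, c_out, k, k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def out_size(self, h: int) -> int:
        return self.stride * (h - 1) + self.k - 2 * self.pad + self.out_pad

    def forward(self, x):
        n, c, h, w = x.shape
        self._x = x
        oh, ow = self.out_size(h), self.out_size(w)
        wmat = self.params["W"].reshape(self.c_in, -1)  # (Cin, Cout*k*k)
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        cols = xf @ wmat  # (N*H*W, Cout*k*k)
        out = _col2im(
            cols, (n, self.c_out, oh, ow), self.k, self.stride, self.pad
        )
        # _col2im expects cols indexed by *input* positions of the dual conv;
        # the dual conv of this layer maps (oh, ow) -> (h, w), which is exactly
        # how cols is laid out here.
        return out + self.params["b"][None, :, None, None]

    def backward(self, grad):
        n, c, h, w = self._x.shape
        gcols, (gh, gw) = _im2col(grad, self.k, self.stride, self.pad)
        assert (gh, gw) == (h, w), "transposed-conv geometry mismatch"
        wmat = self.params["W"].reshape(self.c_in, -1)
        xf = self._x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.grads["W"][...] = (xf.T @ gcols).reshape(self.params["W"].shape)
        self.grads["b"][...] = grad.sum(axis=(0, 2, 3))
        dx = gcols @ wmat.T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y * self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_items(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{i}.{name}", p, layer.grads[name]


def make_activation(name: str) -> Layer:
    table = {"relu": ReLU, "sigmoid": Sigmoid, "tanh": Tanh}
    try:
        return table[name]()
    except KeyError:  # pragma: no cover - config validation catches earlier
        raise ValueError(f"unknown activation {name!r}") from None
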