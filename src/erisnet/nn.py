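"""Minimal convolutional-network building blocks in NumPy.

Two surfaces live here:

* **Reference kernels** (:func:`convolve2d`, :func:`relu`, :func:`maxpool2d`,
  :func:`batchnorm`, :func:`dropout_mask`) — direct transcriptions of the
  layer mathematics on plain 2-D arrays, used as the testable definition of
  each operation.
* **Layer classes** — batched (N, C, H, W) implementations with analytic
  backward passes, built on im2col/BLAS matmuls, which the denoising model
  assembles and the trainer optimises with Adam.

Convolutions follow the cross-correlation convention
``y[i, j] = sum_{m,n} x[i+m, j+n] * w[m, n] + b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "convolve2d",
    "relu",
    "maxpool2d",
    "batchnorm",
    "dropout_mask",
    "Parameter",
    "Conv2D",
    "ConvTranspose2x2",
    "ReLU",
    "MaxPool2x2",
    "BatchNorm2D",
    "Dropout",
    "Adam",
]


# ---------------------------------------------------------------------------
# Reference kernels on 2-D arrays


def convolve2d(
    x: np.ndarray, w: np.ndarray, b: float = 0.0, padding: str = "valid"
) -> np.ndarray:
    """Cross-correlate a 2-D input with a 2-D kernel plus a scalar bias.

    ``padding='same'`` zero-pads so the output matches the input shape
    (odd kernels only); ``'valid'`` returns the fully-overlapping region.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    kh, kw = w.shape
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("'same' padding requires odd kernel sizes")
        x = np.pad(x, ((kh // 2, kh // 2), (kw // 2, kw // 2)))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if x.shape[0] < kh or x.shape[1] < kw:
        raise ValueError(f"kernel {w.shape} does not fit input {x.shape}")
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw))
    return np.einsum("ijmn,mn->ij", win, w) + b


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, np.asarray(x))


def maxpool2d(x: np.ndarray, k: int = 2) -> np.ndarray:
    """Non-overlapping k x k max pooling of a 2-D array (shape divisible by k)."""
    x = np.asarray(x)
    m, n = x.shape
    if m % k or n % k:
        raise ValueError(f"shape {x.shape} not divisible by pool size {k}")
    return x.reshape(m // k, k, n // k, k).max(axis=(1, 3))


def batchnorm(
    x: np.ndarray,
    mean: float | np.ndarray | None = None,
    var: float | np.ndarray | None = None,
    eps: float = 1e-5,
) -> np.ndarray:
    """Normalise to zero mean / unit variance: (x - mu) / sqrt(sigma^2 + eps).

    When mean/var are omitted they are computed from ``x`` itself
    (population statistics), as during training.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean() if mean is None else mean
    s2 = x.var() if var is None else var
    return (x - mu) / np.sqrt(s2 + eps)


def dropout_mask(
    shape: tuple[int, ...], p: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability p, else 1/(1-p).

    Multiplying activations by this mask keeps their expectation unchanged,
    so inference needs no rescaling.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    if p == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p).astype(float) / (1.0 - p)


# ---------------------------------------------------------------------------
# Batched layers with backward passes

# im2col buffers larger than this are processed in row chunks (bytes).
_COL_BYTES_CAP = 256 * 2**20


@dataclass
class Parameter:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class; layers cache what their backward pass needs."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution on (N, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, name: str = "conv"):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for shape-preserving padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = Parameter(_he_uniform(rng, (c_out, c_in, k, k), c_in * k * k), name=f"{name}.w")
        self.b = Parameter(np.zeros(c_out, dtype=np.float32), name=f"{name}.b")
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        wmat = self.w.value.reshape(self.c_out, -1).T  # (c*k*k, c_out)
        col_bytes = n * h * w * c * self.k * self.k * x.dtype.itemsize
        if training or col_bytes <= _COL_BYTES_CAP:
            cols = self._im2col(x)
            y = cols @ wmat
            if training:
                self._cols, self._x_shape = cols, x.shape
        else:
            # inference on large images: chunk over output rows
            y = np.empty((n * h * w, self.c_out), dtype=x.dtype)
            rows_per_chunk = max(1, _COL_BYTES_CAP // max(1, n * w * c * self.k * self.k * x.dtype.itemsize))
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            for i0 in range(0, h, rows_per_chunk):
                i1 = min(h, i0 + rows_per_chunk)
                sub = xp[:, :, i0 : i1 + 2 * p, :]
                win = np.lib.stride_tricks.sliding_window_view(sub, (self.k, self.k), axis=(2, 3))
                cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                    n * (i1 - i0) * w, -1
                )
                blk = (cols @ wmat).reshape(n, i1 - i0, w, self.c_out)
                y.reshape(n, h, w, self.c_out)[:, i0:i1] = blk
        y = y.reshape(n, h, w, self.c_out) + self.b.value
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._x_shape is not None, "forward(training=True) first"
        n, c, h, w = self._x_shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.w.grad += (dy_mat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dy_mat.sum(axis=0)
        # dx = 'same' correlation of dy with the flipped, channel-transposed kernel
        wt = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, -1)
        dx = cols @ wt.reshape(self.c_in, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ConvTranspose2x2(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = "convT"):
        self.c_in, self.c_out = c_in, c_out
        self.w = Parameter(_he_uniform(rng, (c_in, c_out, 2, 2), c_in), name=f"{name}.w")
        self.b = Parameter(np.zeros(c_out, dtype=np.float32), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        y6 = np.einsum("ncij,cdpq->ndipjq", x, self.w.value, optimize=True)
        y = y6.reshape(n, self.c_out, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if training:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        n, d, h2, w2 = dy.shape
        dy6 = dy.reshape(n, d, h2 // 2, 2, w2 // 2, 2)
        self.w.grad += np.einsum("ncij,ndipjq->cdpq", self._x, dy6, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("ndipjq,cdpq->ncij", dy6, self.w.value, optimize=True)
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(0, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        if training:
            self._idx = x4.argmax(axis=-1)
            self._shape = x.shape
        return x4.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._shape is not None
        n, c, h, w = self._shape
        dx4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dx4, self._idx[..., None], dy[..., None], axis=-1)
        return (
            dx4.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with learnable scale/shift and
    running statistics for inference."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(c, dtype=np.float32), name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv, shape = self._cache
        n_elem = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        dx = (
            inv[None, :, None, None]
            / n_elem
            * (
                n_elem * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        self._mask = dropout_mask(x.shape, self.p, self.rng).astype(np.float32)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
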