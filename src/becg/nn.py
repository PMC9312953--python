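"""Numpy building blocks for the binary convolutional auto-encoder.

Every operator here exists in two guises: a small functional form
(:func:`conv1d`, :func:`maxpool`, ...) used directly in tests and simple
scripts, and a stateful layer class with an explicit ``forward``/``backward``
pair used by the training loop.  Backpropagation is hand-written; the binary
encoding layer uses a straight-through surrogate: its forward pass is the
hard step function and its backward pass multiplies the downstream gradient
by the indicator of the pre-activation lying in [-0.5, 0.5).

Array layout is channels-last: ``(batch, length, channels)``.  Convolutions
are stride-1 with "same" symmetric zero padding (``kernel_size - 1`` total,
the left side getting the floor), realized as one GEMM per kernel tap so the
heavy lifting stays inside BLAS.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "step_activation",
    "step_surrogate_gradient",
    "conv1d",
    "tconv1d",
    "maxpool",
    "upsample_zero",
    "linear_out",
    "Conv1D",
    "TConv1D",
    "MaxPool",
    "UpsampleZero",
    "BinaryEncoding",
    "Dense",
    "Dropout",
    "glorot_uniform",
]


# ---------------------------------------------------------------------------
# functional operators


def step_activation(x: np.ndarray) -> np.ndarray:
    """Hard step: 0 for x < 0, 1 for x >= 0."""
    return (np.asarray(x) >= 0).astype(float)


def step_surrogate_gradient(x: np.ndarray) -> np.ndarray:
    """Surrogate derivative of the step: 1 on [-0.5, 0.5), 0 elsewhere."""
    x = np.asarray(x)
    return ((x >= -0.5) & (x < 0.5)).astype(float)


def _as_blc(x: np.ndarray) -> Tuple[np.ndarray, int]:
    """Promote (L,), (L, C) or (B, L, C) input to (B, L, C); report ndim."""
    x = np.asarray(x, dtype=float)
    nd = x.ndim
    if nd == 1:
        x = x[None, :, None]
    elif nd == 2:
        x = x[None, :, :]
    elif nd != 3:
        raise ValueError("expected 1-, 2- or 3-dimensional input")
    return x, nd


def _as_kio(w: np.ndarray) -> np.ndarray:
    """Promote a kernel to (K, C_in, C_out)."""
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[:, None, None]
    elif w.ndim != 3:
        raise ValueError("kernel must be (K,) or (K, C_in, C_out)")
    return w


def _restore(y: np.ndarray, nd: int) -> np.ndarray:
    if nd == 1:
        return y[0, :, 0] if y.shape[2] == 1 else y[0]
    if nd == 2:
        return y[0]
    return y


def _conv_core(x: np.ndarray, w: np.ndarray, pad_left: int) -> np.ndarray:
    """Stride-1 cross-correlation with explicit left padding, 'same' length."""
    b, length, cin = x.shape
    k, wcin, cout = w.shape
    if wcin != cin:
        raise ValueError(f"kernel expects {wcin} input channels, got {cin}")
    xp = np.zeros((b, length + k - 1, cin), dtype=x.dtype)
    xp[:, pad_left : pad_left + length] = x
    out = np.zeros((b, length, cout), dtype=x.dtype)
    for tap in range(k):
        out += xp[:, tap : tap + length] @ w[tap]
    return out


def _apply_activation(y: np.ndarray, activation: Optional[str]) -> np.ndarray:
    if activation in (None, "none"):
        return y
    if activation == "tanh":
        return np.tanh(y)
    if activation == "relu":
        return np.maximum(y, 0.0)
    if activation == "step":
        return step_activation(y)
    raise ValueError(f"unknown activation {activation!r}")


def conv1d(
    x: np.ndarray,
    weights: np.ndarray,
    bias: Optional[np.ndarray] = None,
    activation: Optional[str] = None,
) -> np.ndarray:
    """Length-preserving 1-D convolution, f(sum_i x_i * w_ij + b_j)."""
    xb, nd = _as_blc(x)
    w = _as_kio(weights)
    pad_left = (w.shape[0] - 1) // 2
    y = _conv_core(xb, w, pad_left)
    if bias is not None:
        y = y + np.asarray(bias, dtype=float)
    return _restore(_apply_activation(y, activation), nd)


def tconv1d(
    x: np.ndarray,
    weights: np.ndarray,
    bias: Optional[np.ndarray] = None,
    activation: Optional[str] = None,
) -> np.ndarray:
    """Transposed-kernel counterpart of :func:`conv1d` ("same" length).

    Realized as convolution with the spatially reversed kernel, so a
    symmetric kernel makes ``tconv1d`` and ``conv1d`` coincide.
    """
    xb, nd = _as_blc(x)
    w = _as_kio(weights)[::-1]
    pad_left = w.shape[0] - 1 - (w.shape[0] - 1) // 2
    y = _conv_core(xb, np.ascontiguousarray(w), pad_left)
    if bias is not None:
        y = y + np.asarray(bias, dtype=float)
    return _restore(_apply_activation(y, activation), nd)


def maxpool(x: np.ndarray, size: int = 2) -> np.ndarray:
    """Non-overlapping max pooling (stride = window)."""
    xb, nd = _as_blc(x)
    b, length, c = xb.shape
    if length % size != 0:
        raise ValueError(f"length {length} not divisible by pool size {size}")
    y = xb.reshape(b, length // size, size, c).max(axis=2)
    return _restore(y, nd)


def upsample_zero(x: np.ndarray, size: int = 2) -> np.ndarray:
    """Zero-padding up-sampling: first slot of each window carries the value."""
    xb, nd = _as_blc(x)
    b, length, c = xb.shape
    y = np.zeros((b, length * size, c), dtype=xb.dtype)
    y[:, ::size] = xb
    return _restore(y, nd)


def linear_out(x: np.ndarray, weights: np.ndarray, bias: Optional[np.ndarray] = None) -> np.ndarray:
    """Affine map with no activation (the decoder's amplitude-restoring head)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    y = x @ w
    if bias is not None:
        y = y + np.asarray(bias, dtype=float)
    return y


def glorot_uniform(
    rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# layer classes (training path)


class Layer:
    """Minimal layer contract: forward/backward plus parameter dictionaries."""

    name: str = ""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}

    def init(self, rng: np.random.Generator) -> None:  # noqa: B027
        pass

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        """Symbolic (length, channels) trace used to validate architectures."""
        return shape


class _BatchNormState:
    """Per-channel batch normalization folded into conv layers."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.g_gamma = np.zeros(channels)
        self.g_beta = np.zeros(channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = tuple(range(grad.ndim - 1))
        m = np.prod([shape[a] for a in axes])
        self.g_gamma = (grad * xhat).sum(axis=axes)
        self.g_beta = grad.sum(axis=axes)
        gx = (self.gamma * inv / m) * (
            m * grad - self.g_beta - xhat * self.g_gamma
        )
        return gx


class _ConvBase(Layer):
    """Shared machinery for Conv1D / TConv1D: GEMM-per-tap conv with optional
    batch norm and activation, plus the matching hand-derived backward pass."""

    transposed = False

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        activation: Optional[str] = "tanh",
        batchnorm: bool = False,
        name: str = "",
    ):
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel_size
        self.activation = activation
        self.name = name
        self.W = np.zeros((kernel_size, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.bn = _BatchNormState(out_channels) if batchnorm else None
        self._cache = None

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.k * self.cin
        fan_out = self.k * self.cout
        self.W = glorot_uniform(rng, self.W.shape, fan_in, fan_out)
        self.b = np.zeros(self.cout)

    def _pad_left(self) -> int:
        if self.transposed:
            return self.k - 1 - (self.k - 1) // 2
        return (self.k - 1) // 2

    def _kernel(self) -> np.ndarray:
        return self.W[::-1] if self.transposed else self.W

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = self._kernel()
        pl = self._pad_left()
        b, length, cin = x.shape
        xp = np.zeros((b, length + self.k - 1, cin), dtype=x.dtype)
        xp[:, pl : pl + length] = x
        z = np.zeros((b, length, self.cout), dtype=x.dtype)
        for tap in range(self.k):
            z += xp[:, tap : tap + length] @ w[tap]
        z += self.b
        if self.bn is not None:
            z = self.bn.forward(z, training)
        if self.activation == "tanh":
            y = np.tanh(z)
        elif self.activation in (None, "none"):
            y = z
        else:
            raise ValueError(f"unsupported conv activation {self.activation!r}")
        if training:
            self._cache = (xp, y if self.activation == "tanh" else None, length)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, tanh_out, length = self._cache
        if tanh_out is not None:
            grad = grad * (1.0 - tanh_out * tanh_out)
        if self.bn is not None:
            grad = self.bn.backward(grad)
        self.gb = grad.sum(axis=(0, 1))
        w = self._kernel()
        gw = np.empty_like(w)
        gxp = np.zeros_like(xp)
        for tap in range(self.k):
            gw[tap] = np.tensordot(xp[:, tap : tap + length], grad, axes=([0, 1], [0, 1]))
            gxp[:, tap : tap + length] += grad @ w[tap].T
        self.gW = gw[::-1] if self.transposed else gw
        pl = self._pad_left()
        return gxp[:, pl : pl + length]

    def params(self) -> Dict[str, np.ndarray]:
        p = {"W": self.W, "b": self.b}
        if self.bn is not None:
            p.update(
                gamma=self.bn.gamma,
                beta=self.bn.beta,
                running_mean=self.bn.running_mean,
                running_var=self.bn.running_var,
            )
        return p

    def grads(self) -> Dict[str, np.ndarray]:
        g = {"W": self.gW, "b": self.gb}
        if self.bn is not None:
            g.update(gamma=self.bn.g_gamma, beta=self.bn.g_beta)
        return g

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        length, channels = shape
        if channels != self.cin:
            raise ValueError(
                f"layer {self.name}: expected {self.cin} input channels, got {channels}"
            )
        return (length, self.cout)


class Conv1D(_ConvBase):
    transposed = False


class TConv1D(_ConvBase):
    transposed = True


class MaxPool(Layer):
    def __init__(self, size: int = 2, name: str = ""):
        self.size = size
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, length, c = x.shape
        if length % self.size:
            raise ValueError(f"length {length} not divisible by pool size {self.size}")
        xr = x.reshape(b, length // self.size, self.size, c)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if training:
            self._cache = (idx, x.shape)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        b, length, c = shape
        gx = np.zeros((b, length // self.size, self.size, c), dtype=grad.dtype)
        np.put_along_axis(gx, idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return gx.reshape(shape)

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        length, channels = shape
        if length % self.size:
            raise ValueError(f"layer {self.name}: length {length} not divisible by {self.size}")
        return (length // self.size, channels)


class UpsampleZero(Layer):
    def __init__(self, size: int = 2, name: str = ""):
        self.size = size
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, length, c = x.shape
        y = np.zeros((b, length * self.size, c), dtype=x.dtype)
        y[:, :: self.size] = x
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, :: self.size]

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        return (shape[0] * self.size, shape[1])


class BinaryEncoding(Layer):
    """The binary bottleneck: hard step forward, straight-through backward."""

    def __init__(self, name: str = "bel"):
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._cache = x
        return step_activation(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * step_surrogate_gradient(self._cache)

    def output_shape(self, shape: Tuple[int, int]) -> Tuple[int, int]:
        return shape


class Dense(Layer):
    """Fully connected layer on (batch, features) arrays."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        activation: Optional[str] = None,
        name: str = "",
    ):
        self.nin = in_features
        self.nout = out_features
        self.activation = activation
        self.name = name
        self.W = np.zeros((in_features, out_features))
        self.b = np.zeros(out_features)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def init(self, rng: np.random.Generator) -> None:
        if self.activation == "relu":  # He initialization suits rectifiers
            self.W = rng.normal(0.0, np.sqrt(2.0 / self.nin), size=self.W.shape)
        else:
            self.W = glorot_uniform(rng, self.W.shape, self.nin, self.nout)
        self.b = np.zeros(self.nout)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        elif self.activation in (None, "none"):
            y = z
        else:
            raise ValueError(f"unsupported dense activation {self.activation!r}")
        if training:
            self._cache = (x, z)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z = self._cache
        if self.activation == "relu":
            grad = grad * (z > 0)
        self.gW = x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> Dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> Dict[str, np.ndarray]:
        return {"W": self.gW, "b": self.gb}

    def output_shape(self, shape):
        return (self.nout,)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float = 0.25, name: str = ""):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name
        self.rng = np.random.default_rng(0)
        self._mask = None

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask
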