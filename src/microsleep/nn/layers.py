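"""Feed-forward layers with explicit forward/backward passes.

A deliberately compact, dependency-free neural-network core in numpy
(float64).  Conventions follow the usual deep-learning toolkits: temporal
tensors are (batch, channels, length); dense inputs are (..., features);
every layer caches what its backward pass needs during ``forward`` with
``train=True``.

Weight matrices are initialized from a Glorot normal distribution,
std = sqrt(2 / (fan_in + fan_out)).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "GaussianNoise",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Dense",
    "Softmax",
    "glorot_normal",
]


def glorot_normal(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_length(self, length: int) -> int:
        """Symbolic temporal-shape propagation (identity unless overridden)."""
        return length


class GaussianNoise(Layer):
    """Adds N(0, sd²) noise during training only (input robustness)."""

    def __init__(self, sd: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.sd = float(sd)
        self.rng = rng

    def forward(self, x, train=False):
        if train and self.sd > 0:
            return x + self.rng.normal(0.0, self.sd, size=x.shape)
        return x

    def backward(self, gy):
        return gy


class Conv1d(Layer):
    """1-D convolution, kernel 3 by default, stride 1.

    ``padding='valid'`` (the default) shortens the output by kernel−1
    samples; ``padding='same'`` zero-pads to preserve length (used only by
    the appended feature layer).
    """

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator,
                 kernel: int = 3, padding: str = "valid") -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_channels, self.filters, self.kernel = in_channels, filters, kernel
        self.padding = padding
        fan_in = in_channels * kernel
        fan_out = filters * kernel
        self.params = {
            "W": glorot_normal(rng, (filters, in_channels, kernel), fan_in, fan_out),
            "b": np.zeros(filters),
        }
        self._cols: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        return length if self.padding == "same" else length - (self.kernel - 1)

    def _pad(self, x):
        if self.padding == "same":
            lo = (self.kernel - 1) // 2
            hi = self.kernel - 1 - lo
            return np.pad(x, ((0, 0), (0, 0), (lo, hi)))
        return x

    def forward(self, x, train=False):
        xp = self._pad(x)
        cols = sliding_window_view(xp, self.kernel, axis=2)  # (B, C, L', K)
        y = np.einsum("bclk,fck->bfl", cols, self.params["W"], optimize=True)
        y += self.params["b"][:, None]
        if train:
            self._cols = cols
        return y

    def backward(self, gy):
        W = self.params["W"]
        self.grads["W"] = np.einsum("bclk,bfl->fck", self._cols, gy, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2))
        k = self.kernel
        gpad = np.pad(gy, ((0, 0), (0, 0), (k - 1, k - 1)))
        wins = sliding_window_view(gpad, k, axis=2)  # (B, F, Lpad, K)
        gx_full = np.einsum("bflk,fck->bcl", wins, W[:, :, ::-1], optimize=True)
        if self.padding == "same":
            lo = (k - 1) // 2
            L = gx_full.shape[2] - (k - 1)
            return gx_full[:, :, lo : lo + L]
        return gx_full


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Running statistics (momentum 0.9) are used at inference time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x, train=False):
        g = self.params["gamma"][:, None]
        b = self.params["beta"][:, None]
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[:, None]) * inv[:, None]
            self._cache = (xhat, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[:, None]) * inv[:, None]
        return g * xhat + b

    def backward(self, gy):
        xhat, inv = self._cache
        g = self.params["gamma"][:, None]
        m = gy.shape[0] * gy.shape[2]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = gy.sum(axis=(0, 2))
        dxhat = gy * g
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[:, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max-pooling; an odd trailing sample is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def out_length(self, length: int) -> int:
        return length // self.size

    def forward(self, x, train=False):
        s = self.size
        L2 = x.shape[2] // s
        xr = x[:, :, : L2 * s].reshape(x.shape[0], x.shape[1], L2, s)
        idx = xr.argmax(axis=3)
        if train:
            self._idx, self._in_len = idx, x.shape[2]
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, gy):
        B, C, L2 = gy.shape
        s = self.size
        gr = np.zeros((B, C, L2, s))
        np.put_along_axis(gr, self._idx[..., None], gy[..., None], axis=3)
        gx = np.zeros((B, C, self._in_len))
        gx[:, :, : L2 * s] = gr.reshape(B, C, L2 * s)
        return gx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x, train=False):
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    """Affine map on the last axis (works for (B, D) and (B, T, D))."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": glorot_normal(rng, (in_features, units), in_features, units),
            "b": np.zeros(units),
        }

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = gy.reshape(-1, gy.shape[-1])
        self.grads["W"] = x2.T @ g2
        self.grads["b"] = g2.sum(axis=0)
        return gy @ self.params["W"].T


class Softmax(Layer):
    """Probability head over the last axis."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if train:
            self._p = p
        return p

    def backward(self, gy):
        p = self._p
        return p * (gy - (gy * p).sum(axis=-1, keepdims=True))
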