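"""Minimal differentiable layer stack used by the fixture networks.

All layers operate on float64 NHWC batches (or (N, F) matrices for dense
layers), cache whatever the backward pass needs, and are fully deterministic.
Channels-last keeps every im2col gather and col2im scatter contiguous in the
innermost axis, which is what makes a pure-numpy stack fast enough here.
This is deliberately small: the networks it has to support are 3–4 block
CNNs on 32x32 images, so clarity and bitwise reproducibility win over
throughput tricks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dense",
    "Flatten",
    "Reshape",
    "Sigmoid",
    "Softplus",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: forward caches, backward consumes the cache."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix, stride 1, 'same' padding."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    n, h, w, c = x.shape
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c)


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image shape."""
    n, h, w, c = shape
    gpad = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=cols.dtype)
    cols = cols.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            gpad[:, i : i + h, j : j + w, :] += cols[:, :, :, i, j, :]
    return gpad[:, pad : pad + h, pad : pad + w, :]


class Conv2d(Layer):
    """Stride-1 'same' convolution (cross-correlation), square kernel."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init, ReLU nets
        self.w = rng.normal(0.0, scale, size=(fan_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col(x, self.k, self.pad)
        out = cols @ self.w + self.b
        n, h, w, _ = x.shape
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, _ = xshape
        gflat = gout.reshape(n * h * w, self.c_out)
        self.gw += cols.T @ gflat
        self.gb += gflat.sum(axis=0)
        gcols = gflat @ self.w.T
        return _col2im(gcols, xshape, self.k, self.pad)

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gw, self.gb]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling; ties route the gradient to the first maximal element."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // 2, w // 2, c, 4)
        self._arg = np.argmax(win, axis=-1)
        self._xshape = x.shape
        return np.max(win, axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        gwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=gout.dtype)
        np.put_along_axis(gwin, self._arg[..., None], gout[..., None], axis=-1)
        gwin = gwin.reshape(n, h // 2, w // 2, c, 2, 2)
        gwin = gwin.transpose(0, 1, 4, 2, 5, 3)  # (n, h2, 2, w2, 2, c)
        return np.ascontiguousarray(gwin).reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, h, w, c = gout.shape
        return gout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample target shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gw += gout.T @ self._x
        self.gb += gout.sum(axis=0)
        return gout @ self.w

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gw, self.gb]


class Softplus(Layer):
    """log(1 + e^x): smooth non-negative activation."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.logaddexp(np.zeros(1, dtype=x.dtype), x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout / (1.0 + np.exp(-self._x))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._y * (1.0 - self._y)


class Sequential:
    """Ordered layer container with explicit forward/backward over a prefix."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in reversed(self.layers[:upto]):
            gout = layer.backward(gout)
        return gout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Adam:
    """Standard Adam on a fixed parameter list; state order is fixed, so
    updates are bitwise deterministic."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
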