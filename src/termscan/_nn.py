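"""Minimal NumPy neural-network engine for the two small CNN topologies.

Implements exactly the pieces the classifiers need: valid-padding 1-D/2-D
convolutions (im2col + matmul), max-pooling, inverted dropout, dense layers,
Glorot-uniform initialisation, the Adamax optimizer and binary cross-entropy.
Everything is float32 and deterministic given a seeded Generator (dropout
masks and weight init draw from the caller's rng; batch order is the
caller's responsibility).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv1D",
    "Conv2D",
    "MaxPool1D",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adamax",
    "sigmoid",
    "bce_loss",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    weights: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.weights = []
        self.grads = []

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding stride-1 1-D convolution with ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, input_grad: bool = True):
        super().__init__()
        self.k = kernel
        self.input_grad = input_grad  # False when this is the first layer
        fan_in = kernel * in_channels
        self.W = _glorot(rng, (fan_in, filters), fan_in, kernel * filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.weights = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        OL = L - self.k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        # (B, OL, C, k) -> (B, OL, k*C) matching W rows (k-major, channel-minor)
        patches = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, OL, -1)
        z = patches @ self.W + self.b
        self._patches, self._mask = patches, z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dout):
        dz = np.where(self._mask, dout, 0.0)
        B, OL, F = dz.shape
        self.grads[0][...] = self._patches.reshape(-1, self.W.shape[0]).T @ dz.reshape(-1, F)
        self.grads[1][...] = dz.sum(axis=(0, 1))
        if not self.input_grad:
            return None
        dpatches = (dz @ self.W.T).reshape(B, OL, self.k, -1)
        C = dpatches.shape[-1]
        dx = np.zeros((B, OL + self.k - 1, C), dtype=np.float32)
        for k in range(self.k):
            dx[:, k : k + OL, :] += dpatches[:, :, k, :]
        return dx


@njit(cache=True, fastmath=True)
def _conv2d_fwd(x, W, b, out):  # pragma: no cover - jitted
    # x (B,H,H); W (K,K,F); out (B,F,OH,OW) channels-first; ReLU fused
    B, H, _ = x.shape
    K = W.shape[0]
    F = W.shape[2]
    OH = H - K + 1
    for n in range(B):
        for f in range(F):
            for i in range(OH):
                for j in range(OH):
                    out[n, f, i, j] = b[f]
        for i in range(OH):
            for di in range(K):
                xrow = x[n, i + di]
                for dj in range(K):
                    for f in range(F):
                        w = W[di, dj, f]
                        orow = out[n, f, i]
                        for j in range(OH):
                            orow[j] += w * xrow[dj + j]
        for f in range(F):
            for i in range(OH):
                orow = out[n, f, i]
                for j in range(OH):
                    if orow[j] < 0.0:
                        orow[j] = 0.0


@njit(cache=True, fastmath=True)
def _conv2d_bwd(x, W, act, dout, dx, dW, db, need_dx):  # pragma: no cover
    # act: post-ReLU activations (mask: act > 0); ReLU backward fused.
    # need_dx=False skips the input gradient (the conv is the first layer).
    B, H, _ = x.shape
    K = W.shape[0]
    F = W.shape[2]
    OH = H - K + 1
    dzb = np.empty((F, OH, OH), dtype=np.float32)
    for n in range(B):
        for f in range(F):
            s = np.float32(0.0)
            for i in range(OH):
                arow = act[n, f, i]
                drow = dout[n, f, i]
                zrow = dzb[f, i]
                for j in range(OH):
                    zrow[j] = drow[j] if arow[j] > 0.0 else np.float32(0.0)
                    s += zrow[j]
            db[f] += s
        for i in range(OH):
            for di in range(K):
                xrow = x[n, i + di]
                for dj in range(K):
                    for f in range(F):
                        zrow = dzb[f, i]
                        s = np.float32(0.0)
                        for j in range(OH):
                            s += xrow[dj + j] * zrow[j]
                        dW[di, dj, f] += s
        if need_dx:
            for i in range(OH):
                for di in range(K):
                    dxrow = dx[n, i + di]
                    for dj in range(K):
                        for f in range(F):
                            zrow = dzb[f, i]
                            w = W[di, dj, f]
                            for j in range(OH):
                                dxrow[dj + j] += w * zrow[j]


class Conv2D(Layer):
    """Valid-padding stride-1 square 2-D convolution with ReLU.

    Operates on single-channel (B, H, W) inputs and produces channels-first
    (B, F, OH, OW) activations via cache-blocked jitted kernels; the
    pairing-matrix input is small enough that this direct scheme beats
    im2col by a wide margin on one core.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, input_grad: bool = True):
        super().__init__()
        if in_channels != 1:
            raise ValueError("Conv2D supports a single input channel")
        self.k = kernel
        self.input_grad = input_grad  # False when this is the first layer
        fan_in = kernel * kernel
        self.W = _glorot(
            rng, (kernel, kernel, filters), fan_in, kernel * kernel * filters
        )
        self.b = np.zeros(filters, dtype=np.float32)
        self.weights = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False, rng=None):
        if x.ndim == 4:  # tolerate explicit single-channel layout
            x = x[..., 0]
        x = np.ascontiguousarray(x, dtype=np.float32)
        B, H, _ = x.shape
        OH = H - self.k + 1
        F = self.W.shape[2]
        act = np.empty((B, F, OH, OH), dtype=np.float32)
        _conv2d_fwd(x, self.W, self.b, act)
        self._x, self._act = x, act
        return act

    def backward(self, dout):
        dx = np.zeros_like(self._x) if self.input_grad else np.zeros(
            (0, 0, 0), dtype=np.float32
        )
        self.grads[0][...] = 0.0
        self.grads[1][...] = 0.0
        _conv2d_bwd(
            self._x,
            self.W,
            self._act,
            np.ascontiguousarray(dout, dtype=np.float32),
            dx,
            self.grads[0],
            self.grads[1],
            self.input_grad,
        )
        return dx if self.input_grad else None


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.p = pool

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        OL = L // self.p
        self._in_shape = x.shape
        xr = x[:, : OL * self.p, :].reshape(B, OL, self.p, C).transpose(0, 1, 3, 2)
        self._arg = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dout):
        B, OL, C = dout.shape
        dxr = np.zeros((B, OL, C, self.p), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : OL * self.p, :] = dxr.transpose(0, 1, 3, 2).reshape(B, OL * self.p, C)
        return dx


@njit(cache=True, fastmath=True)
def _maxpool2d_fwd(x, p, out, arg):  # pragma: no cover - jitted
    B, C, H, W = x.shape
    OH = H // p
    OW = W // p
    for n in range(B):
        for c in range(C):
            for i in range(OH):
                for j in range(OW):
                    best = x[n, c, i * p, j * p]
                    besta = 0
                    for a in range(p):
                        for bcol in range(p):
                            v = x[n, c, i * p + a, j * p + bcol]
                            if v > best:
                                best = v
                                besta = a * p + bcol
                    out[n, c, i, j] = best
                    arg[n, c, i, j] = besta


@njit(cache=True, fastmath=True)
def _maxpool2d_bwd(dout, arg, p, dx):  # pragma: no cover - jitted
    B, C, OH, OW = dout.shape
    for n in range(B):
        for c in range(C):
            for i in range(OH):
                for j in range(OW):
                    a = arg[n, c, i, j]
                    dx[n, c, i * p + a // p, j * p + a % p] += dout[n, c, i, j]


class MaxPool2D(Layer):
    """Square max-pooling on channels-first (B, C, H, W) activations."""

    def __init__(self, pool: int):
        super().__init__()
        self.p = pool

    def forward(self, x, training=False, rng=None):
        B, C, H, W = x.shape
        p = self.p
        OH, OW = H // p, W // p
        self._in_shape = x.shape
        out = np.empty((B, C, OH, OW), dtype=np.float32)
        self._arg = np.empty((B, C, OH, OW), dtype=np.int16)
        _maxpool2d_fwd(x, p, out, self._arg)
        return out

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=np.float32)
        _maxpool2d_bwd(
            np.ascontiguousarray(dout, dtype=np.float32), self._arg, self.p, dx
        )
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_units: int, units: int, activation: str,
                 rng: np.random.Generator):
        super().__init__()
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.W = _glorot(rng, (in_units, units), in_units, units)
        self.b = np.zeros(units, dtype=np.float32)
        self.weights = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._cache = z > 0
            return np.where(self._cache, z, 0.0)
        if self.activation == "sigmoid":
            self._cache = sigmoid(z)
            return self._cache
        self._cache = None
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dz = np.where(self._cache, dout, 0.0)
        elif self.activation == "sigmoid":
            a = self._cache
            dz = dout * a * (1.0 - a)
        else:
            dz = dout
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [
            (w, g)
            for layer in self.layers
            for w, g in zip(layer.weights, layer.grads)
        ]

    def count_params(self) -> int:
        return int(sum(w.size for layer in self.layers for w in layer.weights))

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for layer in self.layers for w in layer.weights]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [w for layer in self.layers for w in layer.weights]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match model")
        for dst, src in zip(flat, weights):
            dst[...] = src


class Adamax(Layer):
    """Adamax (infinity-norm variant of Adam); step 2e-3 by default."""

    def __init__(self, params, lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.u = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        correction = 1.0 - self.b1**self.t
        for (w, g), m, u in zip(self.params, self.m, self.u):
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            w -= (self.lr / correction) * m / (u + self.eps)
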