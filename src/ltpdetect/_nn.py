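"""Minimal NumPy neural-network engine for the 3D patch classifier.

Implements exactly the pieces the classifier needs — same-padded 3D
convolution, 2×2×2 max pooling, rectified-linear dense layers, a sigmoid
output trained with binary cross-entropy, and Adam — with explicit
forward/backward passes.  Arrays are float32 throughout and channel-first:
``(batch, channels, depth, height, width)``.

Convolutions are evaluated as one BLAS matrix product over an im2col view,
which keeps CPU training of the small network in the minutes range.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d", "MaxPool3d", "ReLU", "Flatten", "Dense", "Sequential",
    "Adam", "sigmoid", "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy of logits ``z`` against labels ``y``.

    Returns ``(loss, dloss/dz)`` using the overflow-safe form
    ``max(z,0) - z*y + log(1 + exp(-|z|))``.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padded 3D convolution with an odd cubic kernel.

    ``first_layer=True`` skips the input gradient in backward (the data
    needs no gradient), which saves the most expensive col2im of the net.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None,
                 first_layer: bool = False):
        super().__init__()
        self.first_layer = first_layer
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((out_ch, in_ch, kernel, kernel, kernel))
                  * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        # (n, c, d, h, w, k, k, k) view, then (n*dhw, c*k^3) matrix
        win = sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        n, c, d, h, w = x.shape
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * d * h * w, c * self.k**3
        )
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        self._shape = x.shape
        self._cols = self._im2col(x)
        wmat = self.w.reshape(self.out_ch, -1)
        out = self._cols @ wmat.T + self.b
        return out.reshape(n, d, h, w, self.out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        gmat = gy.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        self.grads[0][...] = (gmat.T @ self._cols).reshape(self.w.shape)
        self.grads[1][...] = gmat.sum(axis=0)
        if self.first_layer:
            return np.zeros(self._shape, dtype=np.float32)
        # input gradient = same-padded convolution of gy with the kernel
        # flipped in all spatial axes and transposed in channels
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        gcols = self._im2col(gy)
        wflip = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        gx = gcols @ wflip.reshape(c, -1).T
        return np.ascontiguousarray(
            gx.reshape(n, d, h, w, c).transpose(0, 4, 1, 2, 3)
        )


class MaxPool3d(Layer):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        k = self.k
        if d % k or h % k or w % k:
            raise ValueError(f"pooling {k} does not divide spatial shape {(d, h, w)}")
        xr = x.reshape(n, c, d // k, k, h // k, k, w // k, k)
        out = xr.max(axis=(3, 5, 7))
        # subgradient: ties share the gradient equally
        maxb = out[:, :, :, None, :, None, :, None]
        mask = (xr == maxb)
        self._mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k = self.k
        g = gy[:, :, :, None, :, None, :, None] * self._mask
        return g.reshape(self._shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy):
        self.grads[0][...] = gy.T @ self._x
        self.grads[1][...] = gy.sum(axis=0)
        return (gy @ self.w).astype(np.float32)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
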