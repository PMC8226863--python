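"""Minimal numpy convolutional network with reverse-mode gradients.

Enough machinery to train small beat-image classifiers deterministically on
one CPU: 3x3 same-padding convolutions (im2col), ReLU, 2x2 max pooling,
global average pooling, a dense head, softmax cross-entropy, and Adam.
Everything is float32; all randomness flows through one numpy Generator so a
fixed seed gives bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Flatten", "GlobalAvgPool", "Linear",
           "Sequential", "Adam", "softmax", "softmax_cross_entropy"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H*W, C*k*k)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return xp[:, :, pad:pad + h, pad:pad + w]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 stride-1 same-padding convolution, He-initialised."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        n, hw, _ = self._cols.shape
        h = int(np.sqrt(hw))
        out = self._cols @ self.W.T + self.b
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, h, w = dy.shape
        dy2 = dy.reshape(n, co, h * w).transpose(0, 2, 1)  # (N, HW, C_out)
        self.grads[0][...] = np.einsum("npc,npk->ck", dy2, self._cols)
        self.grads[1][...] = dy2.sum(axis=(0, 1))
        dcols = dy2 @ self.W
        return _col2im(dcols, self._x_shape, self.k, self.k // 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self._xr = xr
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        mask = self._xr == self._out[:, :, :, None, :, None]
        # split gradient evenly among ties (rare with float inputs)
        mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        dx = mask * dy[:, :, :, None, :, None]
        return dx.reshape(n, c, 2 * h2, 2 * w2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / self._hw, self._shape).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
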