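"""Minimal NumPy convolutional-network backend.

Implements exactly the layers the image classifier needs — standard and
depthwise 3x3 convolutions, ReLU, global average pooling and a dense layer —
with explicit forward/backward passes and an Adam optimizer.  Everything is
float32 and fully deterministic given a seeded ``numpy`` Generator: there is
no threading-dependent reduction order beyond BLAS GEMM, no dropout, no
random augmentation.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride s, 'same' padding, NHWC layout."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, stride: int = 1, name: str = "conv"):
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.w = Param(_he_init(rng, (k * k * c_in, c_out), k * k * c_in), f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, s = self.k, self.stride
        pad = k // 2
        n, h, w_in, c = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (n, ho, wo, c, k, k)
        ho, wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, k * k * c
        )
        out = cols @ self.w.value + self.b.value
        self._cache = (cols, (n, h, w_in, c), (ho, wo), xp.shape)
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout):
        cols, (n, h, w_in, c), (ho, wo), xpshape = self._cache
        k, s = self.k, self.stride
        pad = k // 2
        d2 = dout.reshape(n * ho * wo, self.c_out)
        self.w.grad += cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.w.value.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros(xpshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad : pad + h, pad : pad + w_in, :]


class DepthwiseConv2D(Layer):
    """kxk depthwise convolution (one filter per channel), 'same' padding."""

    def __init__(self, rng, c: int, k: int = 3, stride: int = 1, name: str = "dwconv"):
        self.k, self.stride, self.c = k, stride, c
        self.w = Param(_he_init(rng, (k, k, c), k * k), f"{name}.w")
        self.b = Param(np.zeros(c, dtype=np.float32), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, s = self.k, self.stride
        pad = k // 2
        n, h, w_in, c = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        ho = (h + 2 * pad - k) // s + 1
        wo = (w_in + 2 * pad - k) // s + 1
        out = np.zeros((n, ho, wo, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += self.w.value[i, j] * xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
        out += self.b.value
        self._cache = (xp, (n, h, w_in, c), (ho, wo))
        return out

    def backward(self, dout):
        xp, (n, h, w_in, c), (ho, wo) = self._cache
        k, s = self.k, self.stride
        pad = k // 2
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
                self.w.grad[i, j] += (dout * sl).sum(axis=(0, 1, 2))
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dout * self.w.value[i, j]
        self.b.grad += dout.sum(axis=(0, 1, 2))
        return dxp[:, pad : pad + h, pad : pad + w_in, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), self._shape
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, rng, c_in: int, c_out: int, name: str = "dense"):
        self.w = Param(_he_init(rng, (c_in, c_out), c_in), f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
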