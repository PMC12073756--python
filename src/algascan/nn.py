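"""Minimal NumPy neural-network engine for small 1-D convolutional models.

Layers implement ``forward(x, train)`` and ``backward(grad)``; parameters and
their gradients live on the layer as ``params`` / ``grads`` dicts.  The
engine covers exactly what the spectral classifier needs -- 1-D convolution
(im2col), ReLU, max pooling, inverted dropout, dense layers, softmax
cross-entropy, and Adam -- with fully seeded determinism: weight
initialization, batch shuffling, and dropout masks all draw from one
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "cross_entropy",
    "Adam",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, symmetric zero padding."""

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=1, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_channels, in_channels, kernel_size)).astype(np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }

    def forward(self, x, train=False):
        # x: (N, C_in, L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (N, C_in, L_out, k)
        self._cols = cols
        self._in_len = x.shape[2]
        y = np.einsum("oik,nilk->nol", self.params["W"], cols, optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, grad):
        # grad: (N, C_out, L_out)
        self.grads["W"] = np.einsum("nol,nilk->oik", grad, self._cols, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2))
        dcols = np.einsum("oik,nol->nilk", self.params["W"], grad, optimize=True)
        n, ci, lout, k = dcols.shape
        dxp = np.zeros((n, ci, self._in_len + 2 * self.pad), dtype=grad.dtype)
        for j in range(k):
            dxp[:, :, j : j + lout] += dcols[:, :, :, j]
        return dxp[:, :, self.pad : self.pad + self._in_len]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Max pooling with equal size and stride (non-overlapping windows)."""

    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        n, c, l = x.shape
        lo = l // self.size
        xt = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, grad):
        n, c, lo = grad.shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dxt = dx[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        ni, ci, li = np.ogrid[:n, :c, :lo]
        dxt[ni, ci, li, self._argmax] = grad
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p=0.25, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None, relu_init=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt((2.0 if relu_init else 1.0) / in_features)
        self.params = {
            "W": rng.normal(0.0, scale, (out_features, in_features)).astype(np.float32),
            "b": np.zeros(out_features, dtype=np.float32),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """List of (layer, name) handles for all trainable parameters."""
        return [
            (layer, name)
            for layer in self.layers
            for name in layer.params
        ]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(n), targets] + 1e-12).mean())
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer with the standard defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, model: Sequential, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.handles = model.parameters()
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in self.handles]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in self.handles]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name].astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
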