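"""Minimal numpy neural-network layers with hand-written backprop.

Just enough machinery for the splice-site classifier: valid 1D
convolution, ReLU, ceil-mode max pooling, dense layers, softmax
cross-entropy and Adam.  Convolutions are lowered to matrix products
(im2col) so the whole forward/backward path runs through BLAS.  All
parameters live in plain float64 arrays, so models serialize trivially
and training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Conv1D(Layer):
    """Valid cross-correlation: (B, C, L) -> (B, F, L - K + 1).

    He-normal initialization; ``bias`` adds one term per output feature.
    """

    def __init__(self, in_channels: int, out_features: int, kernel_size: int,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_features, in_channels, kernel_size)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None
        self.kernel_size = kernel_size
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dw] + ([self.db] if self.db is not None else [])

    def out_shape(self, in_shape):
        _, length = in_shape
        return (self.w.shape[0], length - self.kernel_size + 1)

    def forward(self, x, train=False):
        batch, channels, length = x.shape
        k = self.kernel_size
        lout = length - k + 1
        # (B, C, L', K) view -> (B*L', C*K) im2col matrix
        win = sliding_window_view(x, k, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            batch * lout, channels * k
        )
        wmat = self.w.reshape(self.w.shape[0], channels * k)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return y.reshape(batch, lout, -1).transpose(0, 2, 1)

    def backward(self, dy):
        batch, channels, length = self._in_shape
        k = self.kernel_size
        nfeat = self.w.shape[0]
        lout = length - k + 1
        dymat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(batch * lout, nfeat)
        self.dw[...] = (dymat.T @ self._cols).reshape(self.w.shape)
        if self.b is not None:
            self.db[...] = dymat.sum(axis=0)
        dcols = (dymat @ self.w.reshape(nfeat, channels * k)).reshape(
            batch, lout, channels, k
        )
        dx = np.zeros((batch, channels, length), dtype=DTYPE)
        for j in range(k):
            dx[:, :, j : j + lout] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class MaxPool1D(Layer):
    """Ceil-mode max pooling: a ragged tail window is kept, not dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def out_shape(self, in_shape):
        channels, length = in_shape
        return (channels, -(-length // self.pool))

    def forward(self, x, train=False):
        batch, channels, length = x.shape
        p = self.pool
        lout = -(-length // p)
        pad = lout * p - length
        if pad:
            x = np.concatenate(
                [x, np.full((batch, channels, pad), -np.inf, dtype=x.dtype)], axis=2
            )
        xr = x.reshape(batch, channels, lout, p)
        idx = xr.argmax(axis=3)
        if train:
            self._idx = idx
            self._in_len = length
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        batch, channels, lout = dy.shape
        p = self.pool
        dxp = np.zeros((batch, channels, lout, p), dtype=DTYPE)
        np.put_along_axis(dxp, self._idx[..., None], dy[..., None], axis=3)
        return dxp.reshape(batch, channels, lout * p)[:, :, : self._in_len]


class Flatten(Layer):
    def out_shape(self, in_shape):
        n = 1
        for d in in_shape:
            n *= d
        return (n,)

    def forward(self, x, train=False):
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim)).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dw] + ([self.db] if self.db is not None else [])

    def out_shape(self, in_shape):
        return (self.w.shape[0],)

    def forward(self, x, train=False):
        if train:
            self._x = x
        y = x @ self.w.T
        if self.b is not None:
            y += self.b
        return y

    def backward(self, dy):
        self.dw[...] = dy.T @ self._x
        if self.b is not None:
            self.db[...] = dy.sum(axis=0)
        return dy @ self.w


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                capture: int | None = None) -> np.ndarray | tuple:
        """Run the stack; optionally also return the output of layer
        ``capture`` (index into ``layers``)."""
        captured = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if capture is not None and i == capture:
                captured = x
        return x if capture is None else (x, captured)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style: the decay
    multiplies the parameter directly and never enters the moments)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        decay = 1.0 - self.lr * self.weight_decay
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            if self.weight_decay:
                p *= decay
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
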