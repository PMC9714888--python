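"""Minimal NumPy neural-network kernels for the temporal convolutional net.

Self-contained forward/backward implementations of the handful of layers
the classifier needs: weight-normalised dilated causal 1-D convolution
(im2col + GEMM), 1x1 channel projection, ReLU, spatial (per-channel)
dropout, global average pooling over time, a dense softmax head, and the
Adam optimiser.  Arrays are (batch, time, channels) in float32; gradients
accumulate on :class:`Param` objects.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "WeightNormConv1d",
    "Conv1x1",
    "SpatialDropout",
    "relu",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "softmax_xent",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col_causal(x: np.ndarray, k: int, d: int) -> np.ndarray:
    """(B, L, Cin) -> (B, L, k, Cin) with left zero-padding of (k-1)*d.

    Tap i (i = 0..k-1) sees the input at lag (k-1-i)*d, so tap k-1 is the
    current sample and the output at t never touches inputs after t.
    """
    B, L, C = x.shape
    pad = (k - 1) * d
    xp = np.concatenate([np.zeros((B, pad, C), dtype=x.dtype), x], axis=1)
    return np.stack([xp[:, i * d : i * d + L, :] for i in range(k)], axis=2)


def _col2im_causal(dcols: np.ndarray, k: int, d: int) -> np.ndarray:
    """Adjoint of :func:`_im2col_causal`."""
    B, L, _, C = dcols.shape
    pad = (k - 1) * d
    dxp = np.zeros((B, L + pad, C), dtype=dcols.dtype)
    for i in range(k):
        dxp[:, i * d : i * d + L, :] += dcols[:, :, i, :]
    return dxp[:, pad:, :]


class WeightNormConv1d:
    """Dilated causal conv with weight normalisation W = g * V / ||V||.

    The norm is taken over the (tap, in-channel) axes per output channel;
    g is initialised to ||V|| so the initial effective kernel equals V.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, dilation: int, rng,
                 init_gain: float = 1.0):
        self.k, self.d = int(k), int(dilation)
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / (k * in_ch))
        v = rng.standard_normal((k, in_ch, out_ch)) * scale
        self.v = Param(v)
        # init_gain < 1 starts the layer near zero (residual blocks open
        # close to the identity, keeping deep stacks stable at init)
        self.g = Param(init_gain * np.sqrt(np.sum(v**2, axis=(0, 1))))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.v, self.g, self.b]

    def weight(self) -> np.ndarray:
        v = self.v.value
        norm = np.sqrt(np.sum(v**2, axis=(0, 1), keepdims=True))
        return self.g.value * v / np.maximum(norm, 1e-12)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W = self.weight()
        cols = _im2col_causal(x, self.k, self.d)
        B, L = x.shape[:2]
        flat = cols.reshape(B * L, self.k * self.in_ch)
        y = flat @ W.reshape(self.k * self.in_ch, self.out_ch) + self.b.value
        if train:
            self._cache = (flat, x.shape, W)
        return y.reshape(B, L, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        flat, xshape, W = self._cache
        B, L, _ = xshape
        dyf = dy.reshape(B * L, self.out_ch)
        dW = (flat.T @ dyf).reshape(self.k, self.in_ch, self.out_ch)
        self.b.grad += dyf.sum(axis=0)
        # chain rule through the weight normalisation
        v = self.v.value
        norm = np.sqrt(np.sum(v**2, axis=(0, 1), keepdims=True))
        norm = np.maximum(norm, 1e-12)
        vn = v / norm
        self.g.grad += np.sum(dW * vn, axis=(0, 1))
        g = self.g.value
        self.v.grad += (g / norm) * (dW - vn * np.sum(dW * vn, axis=(0, 1)))
        dcols = (dyf @ W.reshape(self.k * self.in_ch, self.out_ch).T).reshape(
            B, L, self.k, self.in_ch
        )
        return _col2im_causal(dcols, self.k, self.d)


class Conv1x1:
    """Pointwise channel projection (the residual shortcut when widths differ)."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        scale = np.sqrt(1.0 / in_ch)
        self.W = Param(rng.standard_normal((in_ch, out_ch)) * scale)
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        B, L, ci = x.shape
        self.W.grad += x.reshape(B * L, ci).T @ dy.reshape(B * L, -1)
        self.b.grad += dy.sum(axis=(0, 1))
        return dy @ self.W.value.T


class SpatialDropout:
    """Channel-wise dropout: one Bernoulli mask per (sample, channel)."""

    def __init__(self, rate: float):
        self.rate = float(rate)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.random((x.shape[0], 1, x.shape[2])) < keep) / keep
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class GlobalAvgPool:
    """Mean over the time axis: (B, L, C) -> (B, C)."""

    def __init__(self):
        self._L = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng):
        scale = np.sqrt(1.0 / in_dim)
        self.W = Param(rng.standard_normal((in_dim, out_dim)) * scale)
        self.b = Param(np.zeros(out_dim))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._cache.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, probabilities, and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y_idx)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y_idx], 1e-12))))
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, p, grad / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
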