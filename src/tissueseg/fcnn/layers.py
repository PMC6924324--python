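"""Minimal CPU building blocks for the fully convolutional network.

Convolutions are zero-padded ("same"), stride 1, and implemented as
im2col + BLAS matrix multiplication in float32; the backward pass for the
input is the transposed convolution expressed as a correlation with the
spatially flipped kernel.  Data layout is NHWC throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-kh+1, W-kw+1, kh*kw*C) patch matrix."""
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N, Ho, Wo, kh, kw, C)
    return np.ascontiguousarray(win).reshape(win.shape[:3] + (kh * kw * x.shape[3],))


class Conv2D:
    """Same-padded stride-1 convolution with optional fused ReLU.

    Weights use He-normal initialization, std sqrt(2 / fan_in), biases zero.
    ``W`` has shape (kh*kw*cin, cout), flattened in (kh, kw, cin) order.
    """

    def __init__(self, kernel: int, cin: int, cout: int, rng: np.random.Generator,
                 relu: bool = True):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels are supported with same padding")
        self.kernel = kernel
        self.cin = cin
        self.cout = cout
        self.relu = relu
        fan_in = kernel * kernel * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = None
        self.db = None
        self._col = None
        self._mask = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        if k == 1:
            col = x
        else:
            p = (k - 1) // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            col = _im2col(xp, k, k)
        n, h, w = col.shape[:3]
        y = col.reshape(-1, col.shape[3]) @ self.W + self.b
        y = y.reshape(n, h, w, self.cout)
        if self.relu:
            mask = y > 0
            y *= mask
            if train:
                self._mask = mask
        if train:
            self._col = col
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        k = self.kernel
        dflat = dy.reshape(-1, self.cout)
        self.dW = self._col.reshape(-1, self._col.shape[3]).T @ dflat
        self.db = dflat.sum(axis=0)
        Wr = self.W.reshape(k, k, self.cin, self.cout)
        Wt = Wr[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.cout, self.cin)
        if k == 1:
            dx = dy @ Wt
        else:
            p = (k - 1) // 2
            dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
            col2 = _im2col(dyp, k, k)
            dx = (col2.reshape(-1, k * k * self.cout) @ Wt).reshape(self._in_shape)
        self._col = self._mask = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class MaxPool2:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        r = x[:, : h2 * 2, : w2 * 2]
        r = r.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        r = np.ascontiguousarray(r).reshape(n, h2, w2, 4, c)
        idx = r.argmax(axis=3)
        y = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((n, h2, w2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dr = dr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : h2 * 2, : w2 * 2] = dr.reshape(n, h2 * 2, w2 * 2, c)
        self._idx = None
        return dx

    def params(self):
        return []

    def grads(self):
        return []


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over the last axis, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, target_onehot: np.ndarray):
    """Mean categorical cross entropy and its gradient w.r.t. the logits."""
    eps = 1e-12
    n = probs[..., 0].size
    loss = -float((target_onehot * np.log(probs + eps)).sum()) / n
    dlogits = (probs - target_onehot).astype(np.float32) / n
    return loss, dlogits
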