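"""Minimal feed-forward conv-net primitives with explicit backward passes.

Layout is channels-last throughout: activations are (N, H, W, C) arrays.
Convolutions are 'same' padded, stride 1, implemented as a sum of nine
offset matrix products (for a 3x3 kernel), which vectorises well in NumPy
and needs no im2col buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "relu_forward",
    "relu_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "dense_forward",
    "dense_backward",
    "softmax",
    "Adam",
]


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 convolution.

    x: (N, H, Wd, Cin); W: (kh, kw, Cin, Cout); b: (Cout,).
    Returns (out, xp) where xp is the padded input cached for backward.
    """
    kh, kw, cin, cout = W.shape
    ph, pw = kh // 2, kw // 2
    n, H, Wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n, H, Wd, cout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + H, j : j + Wd, :] @ W[i, j]
    out += b
    return out, xp


def conv2d_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray, need_dx: bool = True):
    """Backward pass of conv2d_forward. Returns (dx, dW, db)."""
    kh, kw, cin, cout = W.shape
    n, H, Wd, _ = dout.shape
    dW = np.empty_like(W)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i : i + H, j : j + Wd, :]
            dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    dx = None
    if need_dx:
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + H, j : j + Wd, :] += dout @ W[i, j].T
        ph, pw = kh // 2, kw // 2
        dx = dxp[:, ph : ph + H, pw : pw + Wd, :]
    return dx, dW, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2. H and W must be even."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 requires even spatial dims; got {h}x{w}")
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4))
    # Ties route gradient equally to all maxima (deterministic).
    mask = r == out[:, :, None, :, None, :]
    cnt = mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask, cnt, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, cnt, shape = cache
    g = mask * (dout[:, :, None, :, None, :] / cnt)
    return g.reshape(shape)


def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (N, D); W: (D, K); b: (K,)."""
    return x @ W + b, x


def dense_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray, need_dx: bool = True):
    dW = x.T @ dout
    db = dout.sum(axis=0)
    dx = dout @ W.T if need_dx else None
    return dx, dW, db


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(params[k])
                self._v[k] = np.zeros_like(params[k])
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
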