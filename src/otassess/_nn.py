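"""Minimal numpy autodiff-free NN primitives for the four-branch CNN.

Only what the classifier needs: valid 1-D convolution, non-overlapping
max pooling, ReLU, dropout, linear layers, softmax cross-entropy, and
Adam.  Forward passes cache what backward needs; everything is
deterministic given the caller's ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "maxpool_forward",
    "maxpool_backward",
    "relu_forward",
    "relu_backward",
    "dropout_forward",
    "linear_forward",
    "linear_backward",
    "softmax_cross_entropy",
    "Adam",
    "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid stride-1 1-D convolution (cross-correlation).

    x: (B, C_in, L); W: (C_out, C_in, k); b: (C_out,)
    returns y (B, C_out, L-k+1) and a cache.
    """
    k = W.shape[2]
    cols = sliding_window_view(x, k, axis=2)  # (B, C_in, L_out, k)
    y = np.einsum("bclk,fck->bfl", cols, W, optimize=True) + b[None, :, None]
    return y, (x, W, cols)


def conv1d_backward(dy: np.ndarray, cache):
    x, W, cols = cache
    k = W.shape[2]
    L_out = dy.shape[2]
    dW = np.einsum("bfl,bclk->fck", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    for kk in range(k):
        dx[:, :, kk : kk + L_out] += np.einsum(
            "bfl,fc->bcl", dy, W[:, :, kk], optimize=True
        )
    return dx, dW, db


def maxpool_forward(x: np.ndarray, window: int):
    """Non-overlapping max pooling along the last axis (no padding; the
    remainder is cropped)."""
    B, C, L = x.shape
    n = L // window
    xt = x[:, :, : n * window].reshape(B, C, n, window)
    idx = xt.argmax(axis=3)
    y = np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]
    return y, (x.shape, window, idx)


def maxpool_backward(dy: np.ndarray, cache):
    shape, window, idx = cache
    B, C, L = shape
    n = L // window
    dxt = np.zeros((B, C, n, window), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(shape, dtype=dy.dtype)
    dx[:, :, : n * window] = dxt.reshape(B, C, n * window)
    return dx


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def dropout_forward(x: np.ndarray, p: float, train: bool, rng: np.random.Generator):
    if not train or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, (x, W)


def linear_backward(dy: np.ndarray, cache):
    x, W = cache
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch; targets are class indices.

    Returns (loss, dlogits).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), targets] + 1e-12).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
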