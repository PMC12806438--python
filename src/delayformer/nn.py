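"""Minimal NumPy neural-network kernels with hand-derived gradients.

This module provides exactly the pieces the forecaster's encoder needs —
affine maps, LayerNorm, multi-head self-attention, a ReLU feed-forward pair,
inverted dropout, and Adam — as pure functions operating on float arrays.
Each ``*_forward`` returns ``(output, cache)`` and the matching ``*_backward``
consumes ``(grad_output, cache)``; gradients are validated against central
finite differences in the test suite.

All kernels are shape-polymorphic over leading axes (the last axis is the
feature axis), so a whole batch of token sequences, ``(sequences, tokens,
features)``, flows through a single BLAS call per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "linear_forward",
    "linear_backward",
    "layernorm_forward",
    "layernorm_backward",
    "relu_forward",
    "relu_backward",
    "softmax",
    "mhsa_forward",
    "mhsa_backward",
    "dropout_forward",
    "dropout_backward",
    "AdamState",
]

LN_EPS = 1e-5


def linear_forward(x, W, b):
    """``y = x @ W + b`` over the last axis."""
    return x @ W + b, (x, W)


def linear_backward(dy, cache):
    x, W = cache
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    dW = x2.T @ dy2
    db = dy2.sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


def layernorm_forward(x, g, b, eps=LN_EPS):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    lead = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=lead)
    db = dy.sum(axis=lead)
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy, mask):
    return dy * mask


def softmax(x):
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_inplace(x):
    # caller owns x; mutating saves full-tensor temporaries on the hot path
    x -= x.max(axis=-1, keepdims=True)
    np.exp(x, out=x)
    x /= x.sum(axis=-1, keepdims=True)
    return x


def _split_heads(x, n_heads):
    # (S, T, D) -> (S, h, T, D/h)
    S, T, D = x.shape
    return x.reshape(S, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    # (S, h, T, dh) -> (S, T, h*dh)
    S, h, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(S, T, h * dh)


def mhsa_forward(x, Wqkv, bqkv, Wo, bo, n_heads):
    """Multi-head self-attention on ``x`` of shape ``(S, T, D)``."""
    S, T, D = x.shape
    dh = D // n_heads
    qkv = x @ Wqkv + bqkv  # (S, T, 3D)
    q = _split_heads(qkv[..., :D], n_heads)
    k = _split_heads(qkv[..., D : 2 * D], n_heads)
    v = _split_heads(qkv[..., 2 * D :], n_heads)
    scale = 1.0 / np.sqrt(dh)
    scores = q @ k.transpose(0, 1, 3, 2)  # (S, h, T, T)
    scores *= scale
    p = _softmax_inplace(scores)
    o = p @ v  # (S, h, T, dh)
    merged = _merge_heads(o)
    out = merged @ Wo + bo
    cache = (x, Wqkv, Wo, q, k, v, p, merged, scale, n_heads)
    return out, cache


def mhsa_backward(dout, cache):
    x, Wqkv, Wo, q, k, v, p, merged, scale, n_heads = cache
    S, T, D = x.shape
    dmerged = dout @ Wo.T
    dWo = merged.reshape(-1, D).T @ dout.reshape(-1, D)
    dbo = dout.reshape(-1, D).sum(axis=0)
    do = dmerged.reshape(S, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)
    dp = do @ v.transpose(0, 1, 3, 2)
    dv = p.transpose(0, 1, 3, 2) @ do
    # softmax backward, in place on dp: dscores = p * (dp - sum(dp * p))
    dp -= np.sum(dp * p, axis=-1, keepdims=True)
    dp *= p
    dscores = dp
    dq = dscores @ k
    dq *= scale
    dk = dscores.transpose(0, 1, 3, 2) @ q
    dk *= scale
    dqkv = np.concatenate(
        [_merge_heads(dq), _merge_heads(dk), _merge_heads(dv)], axis=-1
    )  # (S, T, 3D)
    dWqkv = x.reshape(-1, D).T @ dqkv.reshape(-1, 3 * D)
    dbqkv = dqkv.reshape(-1, 3 * D).sum(axis=0)
    dx = dqkv @ Wqkv.T
    return dx, dWqkv, dbqkv, dWo, dbo


def dropout_forward(x, rate, rng):
    """Inverted dropout.  ``rng=None`` or ``rate=0`` means evaluation mode."""
    if rng is None or rate <= 0.0:
        return x, None
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return x * mask, mask


def dropout_backward(dy, mask):
    if mask is None:
        return dy
    return dy * mask


class AdamState:
    """Adam optimizer over a flat ``{name: array}`` parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
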