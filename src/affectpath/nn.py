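"""Sequence-model building blocks: positional encoding, scaled dot-product
attention, multi-head attention, a bidirectional LSTM, linear layers,
dropout and an Adam optimizer — all on the :mod:`affectpath.autodiff`
tape so training needs no hand-derived layer gradients.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat

MASK_NEG = -1e9


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal position encoding: a (length, dim) matrix.

    entry(pos, 2i) = sin(pos / 10000^(2i/dim)) and entry(pos, 2i+1) =
    cos(pos / 10000^(2i/dim)); position counts sequence index, not wall
    clock.  The caller adds this to the trajectory matrix.
    """
    if length < 1 or dim < 2:
        raise ValueError("need length >= 1 and dim >= 2")
    pos = np.arange(length)[:, None].astype(float)
    two_i = 2.0 * (np.arange(dim) // 2)
    angle = pos / np.power(10000.0, two_i[None, :] / dim)
    pe = np.empty((length, dim))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def scaled_attention(q: Tensor, k: Tensor, v: Tensor,
                     mask: Optional[np.ndarray] = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V, optionally with an additive mask.

    Works on plain matrices (T, d_k) and on batched stacks
    (..., T, d_k); ``mask`` broadcasts against the score matrix and
    should hold 0 for visible and a large negative number for hidden
    keys.
    """
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"Q and K must share d_k, got {q.shape} vs {k.shape}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"K and V must share rows, got {k.shape} vs {v.shape}")
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    if mask is not None:
        scores = scores + Tensor(mask)
    return softmax(scores, axis=-1) @ v


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets (N,) given (N, C)."""
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(targets)), np.asarray(targets, dtype=int)]
    return -picked.mean()


class Module:
    def parameters(self) -> List[Tensor]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> List[Tensor]:
        return [self.W, self.b]


class Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training or self.p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadAttention(Module):
    """Self-attention with n_heads parallel scaled dot-product heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray] = None) -> Tensor:
        """x: (B, T, d_model); key_mask: (B, T) with 1=real, 0=padding."""
        B, T, _ = x.shape

        def split(t: Tensor) -> Tensor:  # (B, T, D) -> (B, H, T, d_k)
            return t.reshape(B, T, self.n_heads, self.d_k).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        mask = None
        if key_mask is not None:
            mask = (1.0 - key_mask)[:, None, None, :] * MASK_NEG
        out = scaled_attention(q, k, v, mask=mask)  # (B, H, T, d_k)
        out = out.swapaxes(1, 2).reshape(B, T, self.d_model)
        return self.wo(out)

    def parameters(self) -> List[Tensor]:
        return [p for lin in (self.wq, self.wk, self.wv, self.wo) for p in lin.parameters()]


class LSTMDirection(Module):
    """One direction of an LSTM; gates packed as (i, f, g, o)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        lim = math.sqrt(6.0 / (d_in + 4 * d_hidden))
        self.Wx = Tensor(rng.uniform(-lim, lim, size=(d_in, 4 * d_hidden)), requires_grad=True)
        lim = math.sqrt(6.0 / (d_hidden + 4 * d_hidden))
        self.Wh = Tensor(rng.uniform(-lim, lim, size=(d_hidden, 4 * d_hidden)), requires_grad=True)
        b = np.zeros(4 * d_hidden)
        b[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        """Run over x (B, T, d_in); return the final hidden state (B, H).

        Padded steps (mask 0) leave the state untouched, so with
        front-padded batches the forward pass ends at the true last step
        and the reverse pass ends at the true first step.
        """
        B, T, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            xt = x[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[:, t][:, None])
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        return h

    def parameters(self) -> List[Tensor]:
        return [self.Wx, self.Wh, self.b]


class BiLSTM(Module):
    """Forward and backward LSTM; final states concatenated to (B, 2H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(d_in, d_hidden, rng)
        self.bwd = LSTMDirection(d_in, d_hidden, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self.fwd(x, mask, reverse=False),
                       self.bwd(x, mask, reverse=True)], axis=-1)

    def parameters(self) -> List[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()


class Adam:
    """Adaptive-moment optimizer; fully deterministic given the tape."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
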