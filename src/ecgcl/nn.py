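"""Minimal neural-network layer library on top of HIPS autograd.

All layers are pure functions ``f(params, x) -> y`` where ``params`` is a
(nested) dict of numpy arrays, so the whole model is differentiable with
``autograd.grad`` with respect to the parameter pytree.  Everything runs in
float32 on the CPU.

Conventions
-----------
* 1-D signals are ``(B, L, C)`` batches: batch, length, channels.
* Convolution weights are ``(k, C_in, C_out)``; the convolution is realised
  as a sum of strided slices times per-tap weight matrices, which autograd
  differentiates without a custom VJP.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.misc.flatten import flatten

DTYPE = np.float32


# ---------------------------------------------------------------------------
# initialisers
# ---------------------------------------------------------------------------

def he_conv(rng: np.random.Generator, k: int, c_in: int, c_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (k * c_in))
    return (rng.standard_normal((k, c_in, c_out)) * std).astype(DTYPE)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (n_in + n_out))
    return (rng.standard_normal((n_in, n_out)) * std).astype(DTYPE)


def zeros(*shape: int) -> np.ndarray:
    return np.zeros(shape, dtype=DTYPE)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


@primitive
def _conv1d_raw(x, w, stride, pad):
    """Valid cross-correlation of padded ``x (B, L, C_in)`` with ``w (k, C_in, C_out)``.

    Registered as an autograd primitive with hand-written, fully vectorised
    VJPs: the generic slice-gradient path (``np.add.at``) is far too slow for
    signal-length inputs.
    """
    pl, pr = pad
    if pl or pr:
        x = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    k = w.shape[0]
    out_len = (x.shape[1] - k) // stride + 1
    hi = 1 + stride * (out_len - 1)
    out = np.tensordot(x[:, 0:hi:stride, :], w[0], axes=(2, 0))
    for j in range(1, k):
        out += np.tensordot(x[:, j : j + hi : stride, :], w[j], axes=(2, 0))
    return out


def _conv1d_vjp_x(ans, x, w, stride, pad):
    def vjp(g):
        pl, pr = pad
        k, c_in, _ = w.shape
        out_len = g.shape[1]
        hi = 1 + stride * (out_len - 1)
        gx = np.zeros((x.shape[0], x.shape[1] + pl + pr, c_in), dtype=g.dtype)
        for j in range(k):
            gx[:, j : j + hi : stride, :] += np.tensordot(g, w[j], axes=(2, 1))
        return gx[:, pl : pl + x.shape[1], :]
    return vjp


def _conv1d_vjp_w(ans, x, w, stride, pad):
    def vjp(g):
        pl, pr = pad
        if pl or pr:
            xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        else:
            xp = x
        k = w.shape[0]
        out_len = g.shape[1]
        hi = 1 + stride * (out_len - 1)
        gw = np.empty_like(w)
        for j in range(k):
            gw[j] = np.tensordot(xp[:, j : j + hi : stride, :], g, axes=([0, 1], [0, 1]))
        return gw
    return vjp


defvjp(_conv1d_raw, _conv1d_vjp_x, _conv1d_vjp_w)


def conv1d(x, w, b, stride: int = 1, pad: Tuple[int, int] = (0, 0)):
    """1-D convolution of ``x (B, L, C_in)`` with ``w (k, C_in, C_out)`` plus bias."""
    return _conv1d_raw(x, w, stride, pad) + b


def dense(x, w, b):
    return anp.dot(x, w) + b


def batchnorm(x, gamma, beta, mean, var, eps: float = 1e-5):
    """Affine batch normalisation with externally supplied statistics."""
    return gamma * (x - mean) / anp.sqrt(var + eps) + beta


def l2_normalize(x, axis: int = -1, eps: float = 1e-12):
    n = anp.sqrt(anp.sum(x * x, axis=axis, keepdims=True) + eps)
    return x / n


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def init_lstm(rng: np.random.Generator, d_in: int, d_hidden: int) -> Dict[str, np.ndarray]:
    b = zeros(4 * d_hidden)
    b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
    b[2 * d_hidden : 3 * d_hidden] = 0.1  # candidate bias: nonzero state even for zero input
    return {
        "wx": glorot(rng, d_in, 4 * d_hidden),
        "wh": glorot(rng, d_hidden, 4 * d_hidden),
        "b": b,
    }


def lstm_sequence(params, x, reverse: bool = False):
    """Run an LSTM over ``x (B, T, D)``; returns hidden states ``(B, T, H)``.

    With ``reverse=True`` the recurrence consumes the sequence from the last
    timestep backwards, and the returned array is re-aligned so that index t
    holds the state after the backward pass has reached position t.
    """
    B, T, _ = x.shape
    H = params["wh"].shape[0]
    xw = anp.tensordot(x, params["wx"], axes=(2, 0))  # (B, T, 4H)
    h = anp.zeros((B, H), dtype=x.dtype)
    c = anp.zeros((B, H), dtype=x.dtype)
    order = range(T - 1, -1, -1) if reverse else range(T)
    outs: List = [None] * T
    for t in order:
        h, c = _lstm_cell(params, xw[:, t, :], h, c, H)
        outs[t] = h
    return anp.stack(outs, axis=1)


def _lstm_cell(params, xw_t, h, c, H):
    gates = xw_t + anp.dot(h, params["wh"]) + params["b"]
    i = sigmoid(gates[:, :H])
    f = sigmoid(gates[:, H : 2 * H])
    g = anp.tanh(gates[:, 2 * H : 3 * H])
    o = sigmoid(gates[:, 3 * H :])
    c = f * c + i * g
    h = o * anp.tanh(c)
    return h, c


def lstm_last(params, x):
    """Final hidden state of an LSTM run over ``x (B, T, D)`` -> ``(B, H)``."""
    B, T, _ = x.shape
    H = params["wh"].shape[0]
    xw = anp.tensordot(x, params["wx"], axes=(2, 0))
    h = anp.zeros((B, H), dtype=x.dtype)
    c = anp.zeros((B, H), dtype=x.dtype)
    for t in range(T):
        h, c = _lstm_cell(params, xw[:, t, :], h, c, H)
    return h


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam over an arbitrary parameter pytree (via autograd's flatten)."""

    def __init__(self, params, lr: float = 1e-3, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        flat, self._unflatten = flatten(params)
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps

    def step(self, params, grads, lr: float | None = None):
        lr = self.lr if lr is None else lr
        p, unflat = flatten(params)
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        p = p - lr * mhat / (np.sqrt(vhat) + self.eps)
        return unflat(p.astype(DTYPE))
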