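"""Minimal neural-network toolkit on top of ``autograd``.

All layers are pure functions of (params, inputs) built from ``autograd.numpy``
primitives, so both first-order gradients (training) and the input-gradient
norms needed by the WGAN gradient penalty — including its second-order
backward through the critic parameters — come from the same reverse-mode
tape.  Parameters are nested dicts/lists of ``numpy`` arrays; optimizers
operate on the flattened vector view.

Convolutions are one-dimensional with odd kernels and 'same' zero padding,
expressed as a sum of tensordots over kernel taps — fast enough at the
sequence lengths this package targets (tens to a few hundred bases) and
fully traceable by autograd.
"""

from __future__ import annotations

import zlib

import autograd.numpy as anp
import numpy as np
from autograd.misc.flatten import flatten

__all__ = [
    "substream",
    "relu",
    "softmax",
    "log_softmax",
    "linear_init",
    "linear_apply",
    "conv1d_init",
    "conv1d_apply",
    "maxpool1d",
    "dropout_mask",
    "cross_entropy",
    "Adam",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a single run seed.

    Every source of randomness in the package (weight init, latent draws,
    interpolation epsilons, shuffles, dropout masks) pulls from one of these,
    so a run is fully determined by its root seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def relu(x):
    return anp.maximum(x, 0.0)


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# layers


def linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    scale = np.sqrt(2.0 / n_in)
    return {"W": rng.normal(0.0, scale, (n_in, n_out)), "b": np.zeros(n_out)}


def linear_apply(p, x):
    return anp.dot(x, p["W"]) + p["b"]


def conv1d_init(rng: np.random.Generator, c_in: int, c_out: int, kernel: int) -> dict:
    if kernel % 2 != 1:
        raise ValueError("conv1d kernels must be odd for 'same' padding")
    scale = np.sqrt(2.0 / (c_in * kernel))
    return {"W": rng.normal(0.0, scale, (c_out, c_in, kernel)), "b": np.zeros(c_out)}


def conv1d_apply(p, x):
    """'same' 1-D convolution; x has shape (batch, c_in, L)."""
    W, b = p["W"], p["b"]
    B, c_in, L = x.shape
    K = W.shape[2]
    pad = K // 2
    zeros = anp.zeros((B, c_in, pad))
    xp = anp.concatenate([zeros, x, zeros], axis=2)
    out = 0.0
    for k in range(K):
        # (B, L, c_out) contribution of tap k
        tap = anp.tensordot(xp[:, :, k : k + L], W[:, :, k], axes=[[1], [1]])
        out = out + tap
    return anp.transpose(out, (0, 2, 1)) + b[None, :, None]


def maxpool1d(x, window: int):
    """Non-overlapping max pooling along the last axis; trailing remainder dropped."""
    B, C, L = x.shape
    L_out = L // window
    if L_out < 1:
        raise ValueError(f"sequence axis of length {L} too short for pool window {window}")
    return anp.max(anp.reshape(x[:, :, : L_out * window], (B, C, L_out, window)), axis=3)


def dropout_mask(rng: np.random.Generator, shape, p: float) -> np.ndarray:
    """Inverted-dropout multiplier; identity when p == 0."""
    if p <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


def cross_entropy(logits, labels):
    """Mean negative log-likelihood of integer labels under softmax(logits)."""
    logp = log_softmax(logits, axis=1)
    return -anp.mean(logp[anp.arange(logits.shape[0]), labels])


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam over a parameter pytree, stateful across steps.

    Defaults follow the usual gradient-penalty-critic recipe: lr 1e-4 and
    moment coefficients (0, 0.9).  Classifier training overrides them.
    """

    def __init__(self, params, lr=1e-4, betas=(0.0, 0.9), eps=1e-8):
        flat, _ = flatten(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0

    def step(self, params, grads):
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1.0 - self.b1) * flat_g
        self.v = self.b2 * self.v + (1.0 - self.b2) * flat_g**2
        mhat = self.m / (1.0 - self.b1**self.t)
        vhat = self.v / (1.0 - self.b2**self.t)
        return unflatten(flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps))

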