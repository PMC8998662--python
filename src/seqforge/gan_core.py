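"""Residual WGAN-GP generator and critic for one-hot DNA.

The generator maps a standard-normal latent vector z (dimension 100 by
default) through Linear(λZ → L·C), a reshape to (L, C), a stack of
pre-activation residual convolution blocks — each [ReLU → Conv1d → ReLU →
Conv1d], with the block output scaled by r ≤ 1 before being added back to
the block input — a Conv1d(C → 4), and a position-wise softmax, so every
output row is a distribution over (A, T, C, G).

The critic is the mirror image: Conv1d(4 → C), the same residual stack, a
flatten, and Linear(L·C → 1).  It has no output nonlinearity: a Wasserstein
critic scores sequences with an unbounded real.  Its 1-Lipschitz constraint
is imposed softly by the gradient penalty
``λ · E[(‖∇x̂ D(x̂)‖₂ − 1)²]`` at random interpolates x̂ between real and
generated batches, with λ = 12.

(The original saturating GAN objective,
``min_G max_D E[log D(x)] + E[log(1 − D(G(z)))]``, is documented here only
as the historical baseline; this module trains the Wasserstein form
``min_G max_D E[D(x)] − E[D(G(z))]`` with the gradient penalty.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import autograd.numpy as anp
import numpy as np
from autograd import grad

from . import nn

__all__ = [
    "GeneratorConfig",
    "CriticConfig",
    "GanLossTerms",
    "Generator",
    "Critic",
    "build_generator",
    "build_critic",
    "sample_latent",
    "critic_loss",
    "generator_loss",
    "gradient_penalty",
]

DEFAULT_LATENT_DIM = 100
DEFAULT_LAMBDA_GP = 12.0


@dataclass
class GeneratorConfig:
    seq_len: int
    latent_dim: int = DEFAULT_LATENT_DIM
    channels: int = 64
    n_res_blocks: int = 5
    res_scale: float = 0.3
    kernel_len: int = 5

    def __post_init__(self):
        if self.latent_dim < 1 or self.seq_len < 1 or self.channels < 1:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.res_scale <= 1.0):
            raise ValueError("res_scale must lie in [0, 1]")


@dataclass
class CriticConfig:
    seq_len: int
    channels: int = 64
    n_res_blocks: int = 5
    res_scale: float = 0.3
    kernel_len: int = 5

    def __post_init__(self):
        if self.seq_len < 1 or self.channels < 1:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.res_scale <= 1.0):
            raise ValueError("res_scale must lie in [0, 1]")


@dataclass
class GanLossTerms:
    """One training step's loss components; the critic minimizes
    ``critic_loss_orig + gradient_penalty``."""

    critic_loss_orig: float
    gradient_penalty: float
    lambda_gp: float
    generator_loss: float

    @property
    def critic_total(self) -> float:
        return self.critic_loss_orig + self.gradient_penalty


def _res_block_init(rng, channels, kernel):
    return {
        "c1": nn.conv1d_init(rng, channels, channels, kernel),
        "c2": nn.conv1d_init(rng, channels, channels, kernel),
    }


def _res_block_apply(p, h, r):
    y = nn.conv1d_apply(p["c2"], nn.relu(nn.conv1d_apply(p["c1"], nn.relu(h))))
    return h + r * y


class Generator:
    """Callable generator; ``gen(z)`` maps a (B, λZ) latent batch to a
    (B, L, 4) soft one-hot batch whose rows sum to 1."""

    def __init__(self, cfg: GeneratorConfig, params):
        self.cfg = cfg
        self.params = params

    @classmethod
    def build(cls, cfg: GeneratorConfig, seed: int = 0) -> "Generator":
        rng = nn.substream(seed, "generator-init")
        L, C = cfg.seq_len, cfg.channels
        params = {
            "lin": nn.linear_init(rng, cfg.latent_dim, L * C),
            "blocks": [
                _res_block_init(rng, C, cfg.kernel_len) for _ in range(cfg.n_res_blocks)
            ],
            "out": nn.conv1d_init(rng, C, 4, cfg.kernel_len),
        }
        return cls(cfg, params)

    def apply(self, params, z):
        # z may be an autograd box (latent search differentiates through it)
        cfg = self.cfg
        h = nn.linear_apply(params["lin"], z)
        h = anp.transpose(anp.reshape(h, (z.shape[0], cfg.seq_len, cfg.channels)), (0, 2, 1))
        for bp in params["blocks"]:
            h = _res_block_apply(bp, h, cfg.res_scale)
        h = nn.conv1d_apply(params["out"], h)  # (B, 4, L)
        return nn.softmax(anp.transpose(h, (0, 2, 1)), axis=2)

    def __call__(self, z):
        return self.apply(self.params, np.atleast_2d(np.asarray(z)))


class Critic:
    """Callable critic; ``critic(x)`` maps a (B, L, 4) batch (hard or soft)
    to B unbounded real scores."""

    def __init__(self, cfg: CriticConfig, params):
        self.cfg = cfg
        self.params = params

    @classmethod
    def build(cls, cfg: CriticConfig, seed: int = 0) -> "Critic":
        rng = nn.substream(seed, "critic-init")
        L, C = cfg.seq_len, cfg.channels
        params = {
            "in": nn.conv1d_init(rng, 4, C, cfg.kernel_len),
            "blocks": [
                _res_block_init(rng, C, cfg.kernel_len) for _ in range(cfg.n_res_blocks)
            ],
            "lin": nn.linear_init(rng, L * C, 1),
        }
        return cls(cfg, params)

    def apply(self, params, x):
        cfg = self.cfg
        if x.shape[1] != cfg.seq_len:
            raise ValueError(f"critic expects length {cfg.seq_len}, got {x.shape[1]}")
        h = nn.conv1d_apply(params["in"], anp.transpose(x, (0, 2, 1)))
        for bp in params["blocks"]:
            h = _res_block_apply(bp, h, cfg.res_scale)
        h = anp.reshape(h, (h.shape[0], -1))
        return nn.linear_apply(params["lin"], h)[:, 0]

    def __call__(self, x):
        # no coercion here: x may be an autograd box inside gradient_penalty
        return self.apply(self.params, x)


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator.build(cfg, seed)


def build_critic(cfg: CriticConfig, seed: int = 0) -> Critic:
    return Critic.build(cfg, seed)


def sample_latent(rng: np.random.Generator, n: int, latent_dim: int = DEFAULT_LATENT_DIM):
    """Standard-normal latent batch of shape (n, latent_dim)."""
    return rng.standard_normal((n, latent_dim))


# ---------------------------------------------------------------------------
# losses


def critic_loss(critic: Callable, real_batch, fake_batch) -> float:
    """Wasserstein critic loss: mean score on fake minus mean score on real.

    Minimizing it pushes real scores up and fake scores down, i.e. performs
    the inner maximization of ``min_G max_D E[D(x)] − E[D(G(z))]``.
    """
    if real_batch.shape[0] == 0 or fake_batch.shape[0] == 0:
        raise ValueError("empty batch")
    return anp.mean(critic(fake_batch)) - anp.mean(critic(real_batch))


def generator_loss(critic: Callable, fake_batch) -> float:
    """Generator loss: negative mean critic score on the generated batch."""
    if fake_batch.shape[0] == 0:
        raise ValueError("empty batch")
    return -anp.mean(critic(fake_batch))


def gradient_penalty(
    critic: Callable,
    real_batch,
    fake_batch,
    lam: float = DEFAULT_LAMBDA_GP,
    rng: np.random.Generator | int | None = None,
    eps: np.ndarray | None = None,
) -> float:
    """Two-sided gradient penalty ``λ·E[(‖∇x̂ D(x̂)‖₂ − 1)²]``.

    x̂ = ε·real + (1−ε)·fake with one ε ~ Uniform(0,1) per batch item; the
    gradient norm is taken over all L×4 entries of each item.  ``critic``
    must be autograd-traceable (any `Critic` or function of autograd.numpy
    ops).  Pass ``eps`` directly to pin the interpolation points.
    """
    real_batch = np.asarray(real_batch, dtype=float)
    fake_batch = np.asarray(fake_batch, dtype=float)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have equal shapes")
    if eps is None:
        if rng is None:
            rng = np.random.default_rng(0)
        elif isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        eps = rng.random(real_batch.shape[0])
    eps = np.asarray(eps, dtype=float).reshape(-1, 1, 1)
    xhat = eps * real_batch + (1.0 - eps) * fake_batch
    return _gp_value(critic, xhat, lam)


def _gp_value(critic, xhat, lam):
    # per-item input gradients via grad of the summed scores (items are
    # independent, so d sum/dx̂ gives each item's own gradient)
    g = grad(lambda x: anp.sum(critic(x)))(xhat)
    norms = anp.sqrt(anp.sum(g * g, axis=(1, 2)) + 1e-18)
    return lam * anp.mean((norms - 1.0) ** 2)
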