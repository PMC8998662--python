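"""Latent-space analyses: interpolation, gradient search, complementation.

Three probes of what a trained generator has learned:

* linear interpolation between two latent points C1 and C2, decoded along
  the affine path — smooth decodings indicate a well-structured latent
  space;
* gradient-based latent search: given a target sequence, minimize the
  position-wise cross-entropy between the generator's output and the
  target from several random restarts, recovering distinct latent points
  that decode to (nearly) the same sequence;
* latent complementation: reflect latent points through the origin
  (z → −z) and tally, position by position, which base the reflected point
  generates for each base the original generated.  A trained generator
  shows a bias toward Watson–Crick complements (A⟷T, G⟷C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import grad

from . import nn
from .gan_core import Generator, sample_latent
from .seqdata import ALPHABET, OneHotSequence, hard_argmax

__all__ = [
    "InterpolationPath",
    "ComplementationReport",
    "interpolate",
    "latent_search",
    "reflect",
    "complementation_report",
]


@dataclass
class InterpolationPath:
    C1: np.ndarray
    C2: np.ndarray
    n_steps: int
    points: np.ndarray  # (n_steps, latent_dim)
    decoded: np.ndarray  # (n_steps, L, 4) soft

    def consensus_strings(self) -> List[str]:
        return ["".join(ALPHABET[i] for i in m.argmax(axis=1)) for m in self.decoded]


@dataclass
class ComplementationReport:
    """Row-stochastic 4×4 matrix: entry (b, b') is the fraction of positions
    generated as base b from z that decode to base b' from −z."""

    matrix: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("complementation rows must sum to 1")

    def complement_fraction(self) -> float:
        """Mass on the Watson–Crick complement cells A→T, T→A, C→G, G→C."""
        # column order (A, T, C, G): complements are the (0,1) and (2,3) swaps
        return float(np.mean([self.matrix[0, 1], self.matrix[1, 0], self.matrix[2, 3], self.matrix[3, 2]]))


def interpolate(generator: Generator, C1, C2, n_steps: int) -> InterpolationPath:
    """Decode the affine path (1−α)·C1 + α·C2, α = t/(n_steps−1).

    The endpoints decode to exactly the generations from C1 and C2.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    C1 = np.asarray(C1, dtype=float).ravel()
    C2 = np.asarray(C2, dtype=float).ravel()
    if C1.shape != C2.shape or C1.size != generator.cfg.latent_dim:
        raise ValueError("latent dimensions do not match the generator")
    alphas = np.linspace(0.0, 1.0, n_steps)
    points = (1.0 - alphas)[:, None] * C1[None, :] + alphas[:, None] * C2[None, :]
    points[0], points[-1] = C1, C2  # exact endpoints, no fp drift
    return InterpolationPath(
        C1=C1, C2=C2, n_steps=n_steps, points=points, decoded=np.asarray(generator(points))
    )


def latent_search(
    generator: Generator,
    target,
    n_restarts: int = 5,
    max_iters: int = 200,
    seed: int = 0,
    lr: float = 0.05,
    tolerance: float = 0.1,
    init: Optional[np.ndarray] = None,
) -> List[Tuple[np.ndarray, float]]:
    """Find latent points whose decoding matches a target sequence.

    Minimizes the mean per-position cross-entropy between generator output
    and the target's hard one-hot by Adam from ``n_restarts`` independent
    standard-normal starts (or a provided ``init``).  Returns the (z, loss)
    pairs achieving a final loss ≤ ``tolerance`` nats/position; may be
    empty if no restart converges.
    """
    t = target.matrix if isinstance(target, OneHotSequence) else np.asarray(target, dtype=float)
    rng = nn.substream(seed, "latent-search")

    def loss(z):
        p = generator.apply(generator.params, anp.reshape(z, (1, -1)))[0]
        return -anp.mean(anp.sum(t * anp.log(p + 1e-12), axis=1))

    gfun = grad(loss)
    results = []
    for r in range(n_restarts):
        if init is not None:
            z = np.asarray(init, dtype=float).ravel().copy()
        else:
            z = rng.standard_normal(generator.cfg.latent_dim)
        opt = nn.Adam(z, lr=lr, betas=(0.9, 0.999))
        for _ in range(max_iters):
            z = opt.step(z, gfun(z))
        final = float(loss(z))
        if final <= tolerance:
            results.append((z, final))
    return results


def reflect(z: np.ndarray) -> np.ndarray:
    """Reflection through the origin, z → −z: a norm-preserving involution."""
    return -np.asarray(z, dtype=float)


def complementation_report(
    generator: Generator, n_samples: int, seed: int = 0
) -> ComplementationReport:
    """Tally base→base transitions between decodings of z and of −z.

    Samples ``n_samples`` standard-normal latents, hard-decodes generator(z)
    and generator(reflect(z)), and accumulates the position-wise 4×4
    contingency table, row-normalized over the base generated from z.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = nn.substream(seed, "complementation")
    z = sample_latent(rng, n_samples, generator.cfg.latent_dim)
    fwd = hard_argmax(np.asarray(generator(z))).argmax(axis=2)
    rev = hard_argmax(np.asarray(generator(reflect(z)))).argmax(axis=2)
    counts = np.zeros((4, 4))
    for b in range(4):
        mask = fwd == b
        for b2 in range(4):
            counts[b, b2] = np.sum(rev[mask] == b2)
    row_sums = counts.sum(axis=1, keepdims=True)
    # a base the generator never emits gets a uniform row
    matrix = np.where(row_sums > 0, counts / np.maximum(row_sums, 1.0), 0.25)
    return ComplementationReport(matrix=matrix, counts=counts)
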