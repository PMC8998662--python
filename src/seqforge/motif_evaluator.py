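"""PWM motif scoring by sliding inner product, and the threshold gate.

A sequence is scored by convolving its L×4 one-hot matrix with a Len×4
probability PWM: at each offset o the score is the inner product
``Σ_j Σ_b pwm[j,b] · seq[o+j,b]``, and max-pooling over offsets keeps the
single best window.  A sequence containing even one strong motif instance
therefore scores high.  The raw maximum is normalized by the PWM's maximum
achievable window score (the sum of per-position column maxima) so that a
fixed threshold — 0.75 by default, chosen over the grid 0.65–0.90 in steps
of 0.05 — is comparable across motifs of different lengths.  The gate
passes sequences with normalized score strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .seqdata import COMPLEMENT_PERM, NucleotideSequence, OneHotSequence, PWM, one_hot_encode

__all__ = [
    "MotifScore",
    "ThresholdConfig",
    "GridPoint",
    "motif_score",
    "score_batch",
    "filter_by_score",
    "grid_search_threshold",
]

DEFAULT_GRID = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90)


@dataclass
class MotifScore:
    raw_max: float
    normalized: float
    best_offset: int


@dataclass
class ThresholdConfig:
    threshold: float = 0.75
    grid: Tuple[float, ...] = DEFAULT_GRID
    scan_revcomp: bool = False

    def __post_init__(self):
        if not all(0.0 < g < 1.0 for g in self.grid):
            raise ValueError("grid values must lie in (0, 1)")


@dataclass
class GridPoint:
    threshold: float
    n_pass: int
    agreement: float


def _as_matrix(seq: Union[NucleotideSequence, OneHotSequence, np.ndarray]) -> np.ndarray:
    if isinstance(seq, NucleotideSequence):
        seq = one_hot_encode(seq, n_policy="uniform")
    m = seq.matrix if isinstance(seq, OneHotSequence) else np.asarray(seq, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError(f"expected an L x 4 matrix, got shape {m.shape}")
    return m


def _window_scores(m: np.ndarray, pwm_matrix: np.ndarray) -> np.ndarray:
    """Inner products of the PWM with every contiguous window [o, o+Len)."""
    L, Len = m.shape[0], pwm_matrix.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(m, (Len, 4))[:, 0]  # (L-Len+1, Len, 4)
    return np.einsum("ojb,jb->o", windows, pwm_matrix)


def motif_score(
    seq: Union[OneHotSequence, np.ndarray], pwm: PWM, scan_revcomp: bool = False
) -> MotifScore:
    """Best-window PWM match of one sequence (hard or soft one-hot).

    Offset ties break toward the smallest offset.  With ``scan_revcomp`` the
    reverse-complement strand is scanned as well and the better strand wins;
    the reported offset stays on the coordinates of the given matrix.
    """
    m = _as_matrix(seq)
    L, Len = m.shape[0], pwm.length
    if L < Len:
        raise ValueError(f"sequence length {L} shorter than motif length {Len}")
    scores = _window_scores(m, pwm.matrix)
    if scan_revcomp:
        rc = m[::-1][:, COMPLEMENT_PERM]
        rc_scores = _window_scores(rc, pwm.matrix)[::-1]
        scores = np.maximum(scores, rc_scores)
    best = int(np.argmax(scores))  # argmax takes the first (smallest) offset on ties
    raw = float(scores[best])
    norm = raw / pwm.max_achievable
    if 1.0 < norm <= 1.0 + 1e-9:  # summation-order rounding overshoot
        norm = 1.0
    return MotifScore(raw_max=raw, normalized=norm, best_offset=best)


def score_batch(batch: np.ndarray, pwm: PWM, scan_revcomp: bool = False):
    """Vectorized scores for a (B, L, 4) batch; returns (raw, normalized, offsets)."""
    batch = np.asarray(batch, dtype=float)
    raws = np.empty(batch.shape[0])
    offs = np.empty(batch.shape[0], dtype=int)
    for i, m in enumerate(batch):
        s = motif_score(m, pwm, scan_revcomp)
        raws[i] = s.raw_max
        offs[i] = s.best_offset
    return raws, raws / pwm.max_achievable, offs


def filter_by_score(
    seqs: Sequence, pwm: PWM, cfg: Optional[ThresholdConfig] = None
) -> Tuple[list, list, List[MotifScore]]:
    """Partition sequences by normalized score strictly above the threshold.

    Order is preserved within both parts; ``scores`` aligns with the input.
    """
    cfg = cfg or ThresholdConfig()
    scores = [motif_score(s, pwm, cfg.scan_revcomp) for s in seqs]
    passed = [s for s, sc in zip(seqs, scores) if sc.normalized > cfg.threshold]
    rejected = [s for s, sc in zip(seqs, scores) if not (sc.normalized > cfg.threshold)]
    return passed, rejected, scores


def grid_search_threshold(
    seqs: Sequence,
    embedded: Sequence[bool],
    pwm: PWM,
    grid: Sequence[float] = DEFAULT_GRID,
    scan_revcomp: bool = False,
) -> List[GridPoint]:
    """Evaluate each candidate threshold against known embed labels.

    For every grid value reports the pass count and the agreement — the
    fraction of sequences where (normalized score > threshold) coincides
    with the motif having been embedded.  Pass counts are non-increasing in
    the threshold by construction.
    """
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    if len(seqs) != len(embedded):
        raise ValueError("labels must align with sequences")
    norm = np.array([motif_score(s, pwm, scan_revcomp).normalized for s in seqs])
    emb = np.asarray(embedded, dtype=bool)
    out = []
    for t in grid:
        passes = norm > t
        out.append(
            GridPoint(
                threshold=float(t),
                n_pass=int(passes.sum()),
                agreement=float(np.mean(passes == emb)),
            )
        )
    return out
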