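"""Fidelity and classification metrics for synthetic-vs-original sequence sets.

Set-level fidelity compares an original and a synthetic sequence set through
a feature matrix — by default the per-position base-frequency profile (a
4×L column-stochastic matrix), optionally a k-mer frequency vector — with:

* Pearson correlation (flattened matrices),
* MAE, mean absolute elementwise error,
* PRD, percent root-mean-square difference
  ``100·√(Σ(Orᵢ−Snᵢ)² / ΣOrᵢ²)`` (normalized by the original, hence
  deliberately asymmetric),
* RMSE, root of the mean squared elementwise error,
* mirror column association: the mean over matrix columns of the Pearson
  correlation between the original and synthetic column, and
* the discrete Fréchet distance between the two matrices read as curves of
  per-column points (minimum over monotone couplings of the maximum
  pointwise euclidean distance, by dynamic programming).

Classifier quality uses the confusion-count statistics Acc, MCC, Sen and
Spc, with Acc/Sen/Spc reported on the 0–100 scale, plus a standard
ROC/AUC sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .seqdata import ALPHABET, BASE_INDEX, NucleotideSequence, one_hot_encode

__all__ = [
    "FeatureMatrix",
    "MetricReport",
    "ConfusionCounts",
    "build_feature_matrix",
    "pearson",
    "mae",
    "prd",
    "rmse",
    "mirror_column_association",
    "frechet_distance",
    "classifier_metrics",
    "roc_curve",
    "compare_datasets",
]


@dataclass
class FeatureMatrix:
    """(n_features × n_columns) summary of a sequence set.

    ``position_freq``: 4 base rows × L position columns, each column a
    distribution.  ``kmer_freq``: 4^k k-mer rows × 1 column summing to 1.
    """

    matrix: np.ndarray
    column_labels: List[str]
    provenance: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class MetricReport:
    pearson: float
    mae: float
    prd: float
    rmse: float
    mirror_column_association: float
    frechet: float
    feature_mode: str = "position_freq"
    n_skipped_columns: int = 0

    def as_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "mae": self.mae,
            "prd": self.prd,
            "rmse": self.rmse,
            "mirror_column_association": self.mirror_column_association,
            "frechet": self.frechet,
        }


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


class AssociationResult(NamedTuple):
    association: float
    n_skipped: int


class ClassifierMetrics(NamedTuple):
    acc: float
    mcc: float
    sen: float
    spc: float


def build_feature_matrix(
    seqs: Sequence[NucleotideSequence], mode: str = "position_freq", k: int = 3
) -> FeatureMatrix:
    """Summarize a sequence set as per-position base frequencies or k-mer frequencies."""
    if not seqs:
        raise ValueError("empty sequence set")
    if mode == "position_freq":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"position_freq requires equal lengths, got {sorted(lengths)}")
        stack = np.stack([one_hot_encode(s, n_policy="uniform").matrix for s in seqs])
        freqs = stack.mean(axis=0)  # (L, 4); rows = positions
        return FeatureMatrix(
            matrix=freqs.T,  # 4 base rows x L position columns
            column_labels=[f"pos{i}" for i in range(freqs.shape[0])],
            provenance="position_freq",
        )
    if mode == "kmer_freq":
        counts = np.zeros(4**k)
        total = 0
        for s in seqs:
            b = s.bases
            for i in range(len(b) - k + 1):
                word = b[i : i + k]
                if "N" in word:
                    continue
                idx = 0
                for ch in word:
                    idx = idx * 4 + BASE_INDEX[ch]
                counts[idx] += 1
                total += 1
        if total == 0:
            raise ValueError("no countable k-mers")
        labels = [""]
        for _ in range(k):
            labels = [w + b for w in labels for b in ALPHABET]
        return FeatureMatrix(
            matrix=(counts / total)[:, None], column_labels=["kmer_freq"], provenance="kmer_freq"
        )
    raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# elementwise fidelity statistics


def _pair(Or, Sn) -> Tuple[np.ndarray, np.ndarray]:
    Or = np.asarray(Or, dtype=float).ravel()
    Sn = np.asarray(Sn, dtype=float).ravel()
    if Or.shape != Sn.shape:
        raise ValueError("inputs must have equal length")
    return Or, Sn


def pearson(Or, Sn) -> float:
    """Product-moment correlation coefficient in [−1, 1]."""
    Or, Sn = _pair(Or, Sn)
    if Or.size < 2:
        raise ValueError("need at least two points")
    do, ds = Or - Or.mean(), Sn - Sn.mean()
    denom = np.sqrt((do**2).sum() * (ds**2).sum())
    if denom == 0.0:
        raise ValueError("undefined correlation: zero variance input")
    return float(np.clip((do * ds).sum() / denom, -1.0, 1.0))


def mae(Or, Sn) -> float:
    Or, Sn = _pair(Or, Sn)
    return float(np.mean(np.abs(Or - Sn)))


def prd(Or, Sn) -> float:
    """Percent RMS difference, normalized by the original's energy."""
    Or, Sn = _pair(Or, Sn)
    ref = (Or**2).sum()
    if ref == 0.0:
        raise ValueError("PRD undefined for an all-zero original")
    return float(100.0 * np.sqrt(((Or - Sn) ** 2).sum() / ref))


def rmse(Or, Sn) -> float:
    Or, Sn = _pair(Or, Sn)
    return float(np.sqrt(np.mean((Or - Sn) ** 2)))


def mirror_column_association(OrM: FeatureMatrix, SnM: FeatureMatrix) -> AssociationResult:
    """Mean per-column Pearson correlation between the two feature matrices.

    Columns where either side has zero variance are skipped; the skip count
    is reported alongside the mean.
    """
    A, B = OrM.matrix, SnM.matrix
    if A.shape != B.shape:
        raise ValueError("feature matrices must share a shape")
    if OrM.column_labels != SnM.column_labels:
        raise ValueError("feature matrices must share column labels")
    vals, skipped = [], 0
    for j in range(A.shape[1]):
        a, b = A[:, j], B[:, j]
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            skipped += 1
            continue
        vals.append(pearson(a, b))
    if not vals:
        raise ValueError("no columns with nonzero variance")
    return AssociationResult(association=float(np.mean(vals)), n_skipped=skipped)


# ---------------------------------------------------------------------------
# discrete Fréchet distance


def frechet_distance(O: np.ndarray, P: np.ndarray) -> float:
    """Discrete Fréchet ("dog-leash") distance between two point sequences.

    The minimum over monotone couplings of the maximum pointwise euclidean
    distance, computed by the O(|O|·|P|) dynamic program.  Points are the
    rows of the inputs; 1-D inputs are treated as sequences of scalars.
    """
    O = np.asarray(O, dtype=float)
    P = np.asarray(P, dtype=float)
    if O.ndim == 1:
        O = O[:, None]
    if P.ndim == 1:
        P = P[:, None]
    if O.size == 0 or P.size == 0:
        raise ValueError("curves must be nonempty")
    if O.shape[1] != P.shape[1]:
        raise ValueError("curves must live in the same dimension")
    n, m = O.shape[0], P.shape[0]
    d = np.sqrt(((O[:, None, :] - P[None, :, :]) ** 2).sum(axis=2))
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[n - 1, m - 1])


# ---------------------------------------------------------------------------
# classifier metrics


def classifier_metrics(c: ConfusionCounts) -> ClassifierMetrics:
    """Acc/Sen/Spc on the 0–100 scale and MCC on [−1, 1].

    MCC is defined as 0 when any denominator factor vanishes; Sen and Spc
    raise when their denominators are 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (c.TP + c.TN) / c.total
    if c.TP + c.FN == 0:
        raise ValueError("sensitivity undefined: no positive examples")
    if c.TN + c.FP == 0:
        raise ValueError("specificity undefined: no negative examples")
    sen = 100.0 * c.TP / (c.TP + c.FN)
    spc = 100.0 * c.TN / (c.TN + c.FP)
    denom2 = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if denom2 == 0 else (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom2)
    return ClassifierMetrics(acc=float(acc), mcc=float(mcc), sen=float(sen), spc=float(spc))


def counts_from_predictions(y_true, y_pred, positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for a given positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def roc_curve(scores, labels) -> Tuple[np.ndarray, float]:
    """(FPR, TPR) points from a threshold sweep plus the trapezoid AUC."""
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# the full report


def compare_datasets(
    original: Sequence[NucleotideSequence],
    synthetic: Sequence[NucleotideSequence],
    mode: str = "position_freq",
    k: int = 3,
) -> MetricReport:
    """All six set-level fidelity metrics between two sequence sets.

    Pearson/MAE/PRD/RMSE act on the flattened feature matrices; the mirror
    column association averages per-column correlations; the Fréchet
    distance treats each matrix as the ordered curve of its column vectors.
    """
    if not original or not synthetic:
        raise ValueError("both sequence sets must be nonempty")
    OrM = build_feature_matrix(original, mode=mode, k=k)
    SnM = build_feature_matrix(synthetic, mode=mode, k=k)
    assoc = mirror_column_association(OrM, SnM)
    return MetricReport(
        pearson=pearson(OrM.matrix, SnM.matrix),
        mae=mae(OrM.matrix, SnM.matrix),
        prd=prd(OrM.matrix, SnM.matrix),
        rmse=rmse(OrM.matrix, SnM.matrix),
        mirror_column_association=assoc.association,
        frechet=frechet_distance(OrM.matrix.T, SnM.matrix.T),
        feature_mode=mode,
        n_skipped_columns=assoc.n_skipped,
    )
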