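"""Layered-CNN promoter classifier and the predictor gate.

The classifier assigns each one-hot sequence to one of four classes — no
promoter, or the sigma-24 / sigma-32 / sigma-54 promoter subtypes — with a
fixed layered architecture: two [Conv1d → ReLU → MaxPool(window 6) →
Dropout(0.5)] stages, a flatten, and one fully-connected softmax head.
``is_promoter`` is true whenever the argmax class is not "none"; the gate
``filter_promoters`` forwards exactly those sequences.  A stratified
k-fold cross-validation (k = 10 by default) reports one-vs-rest confusion
counts and Acc/MCC/Sen/Spc per class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import grad
from sklearn.model_selection import StratifiedKFold

from . import nn
from .eval_metrics import ClassifierMetrics, ConfusionCounts, classifier_metrics, counts_from_predictions
from .seqdata import PROMOTER_CLASSES, NucleotideSequence, OneHotSequence, encode_batch

__all__ = [
    "PredictorConfig",
    "PromoterPrediction",
    "PromoterPredictor",
    "AcceptAllPredictor",
    "RejectAllPredictor",
    "build_predictor",
    "train_predictor",
    "filter_promoters",
    "cross_validate",
]


@dataclass
class PredictorConfig:
    seq_len: int
    conv_channels: Tuple[int, int] = (32, 64)
    kernel_len: Tuple[int, int] = (7, 5)
    pool_window: int = 6
    dropout_p: float = 0.5
    n_classes: int = 4

    def __post_init__(self):
        if self.pool_window < 1:
            raise ValueError("pool_window must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        l1 = self.seq_len // self.pool_window
        l2 = l1 // self.pool_window
        if l2 < 1:
            raise ValueError(
                f"seq_len {self.seq_len} too short for two pool-{self.pool_window} stages"
            )
        self.flat_dim = l2 * self.conv_channels[1]


@dataclass
class PromoterPrediction:
    class_probs: np.ndarray
    predicted_class: str
    is_promoter: bool


class PromoterPredictor:
    """The layered CNN; call ``predict`` for labels or ``predict_proba`` for rows."""

    classes = PROMOTER_CLASSES

    def __init__(self, cfg: PredictorConfig, params):
        self.cfg = cfg
        self.params = params

    @classmethod
    def build(cls, cfg: PredictorConfig, seed: int = 0) -> "PromoterPredictor":
        rng = nn.substream(seed, "predictor-init")
        c1, c2 = cfg.conv_channels
        k1, k2 = cfg.kernel_len
        params = {
            "conv1": nn.conv1d_init(rng, 4, c1, k1),
            "conv2": nn.conv1d_init(rng, c1, c2, k2),
            "fc": nn.linear_init(rng, cfg.flat_dim, cfg.n_classes),
        }
        return cls(cfg, params)

    def architecture(self) -> List[tuple]:
        """Ordered layer echo used for structural checks."""
        cfg = self.cfg
        return [
            ("conv1d", 4, cfg.conv_channels[0], cfg.kernel_len[0]),
            ("relu",),
            ("maxpool", cfg.pool_window),
            ("dropout", cfg.dropout_p),
            ("conv1d", cfg.conv_channels[0], cfg.conv_channels[1], cfg.kernel_len[1]),
            ("relu",),
            ("maxpool", cfg.pool_window),
            ("dropout", cfg.dropout_p),
            ("flatten",),
            ("linear", cfg.n_classes),
            ("softmax",),
        ]

    def apply(self, params, x, dropout_masks=None):
        """Logits for a (B, L, 4) batch; masks enable training-mode dropout."""
        cfg = self.cfg
        h = anp.transpose(x, (0, 2, 1))
        h = nn.maxpool1d(nn.relu(nn.conv1d_apply(params["conv1"], h)), cfg.pool_window)
        if dropout_masks is not None:
            h = h * dropout_masks[0]
        h = nn.maxpool1d(nn.relu(nn.conv1d_apply(params["conv2"], h)), cfg.pool_window)
        if dropout_masks is not None:
            h = h * dropout_masks[1]
        h = anp.reshape(h, (h.shape[0], -1))
        return nn.linear_apply(params["fc"], h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities, rows summing to 1."""
        return np.asarray(nn.softmax(self.apply(self.params, np.asarray(x, dtype=float)), axis=1))

    def predict(self, x: np.ndarray) -> List[PromoterPrediction]:
        probs = self.predict_proba(x)
        out = []
        for row in probs:
            cls = self.classes[int(row.argmax())]
            out.append(
                PromoterPrediction(class_probs=row, predicted_class=cls, is_promoter=cls != "none")
            )
        return out

    def promoter_probability(self, x: np.ndarray) -> np.ndarray:
        """P(any promoter class) = 1 − P(none) per sequence."""
        return 1.0 - self.predict_proba(x)[:, self.classes.index("none")]


class AcceptAllPredictor:
    """Degenerate gate that declares every sequence a promoter (used to
    reduce the feedback loop to a plain WGAN-GP and in short toy runs)."""

    classes = PROMOTER_CLASSES

    def predict(self, x):
        return [
            PromoterPrediction(
                class_probs=np.array([0.0, 1.0, 0.0, 0.0]),
                predicted_class="sigma24",
                is_promoter=True,
            )
            for _ in range(len(x))
        ]

    def predict_proba(self, x):
        return np.tile(np.array([0.0, 1.0, 0.0, 0.0]), (len(x), 1))

    def promoter_probability(self, x):
        return np.ones(len(x))


class RejectAllPredictor:
    """Degenerate gate that rejects everything."""

    classes = PROMOTER_CLASSES

    def predict(self, x):
        return [
            PromoterPrediction(
                class_probs=np.array([1.0, 0.0, 0.0, 0.0]),
                predicted_class="none",
                is_promoter=False,
            )
            for _ in range(len(x))
        ]

    def predict_proba(self, x):
        return np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (len(x), 1))

    def promoter_probability(self, x):
        return np.zeros(len(x))


def build_predictor(cfg: PredictorConfig, seed: int = 0) -> PromoterPredictor:
    return PromoterPredictor.build(cfg, seed)


def _as_batch(seqs) -> np.ndarray:
    if isinstance(seqs, np.ndarray):
        return seqs
    if seqs and isinstance(seqs[0], NucleotideSequence):
        return encode_batch(seqs)
    if seqs and isinstance(seqs[0], OneHotSequence):
        return np.stack([s.matrix for s in seqs])
    return np.asarray(seqs, dtype=float)


def train_predictor(
    predictor: PromoterPredictor,
    X,
    y: Sequence[str],
    epochs: int = 30,
    seed: int = 0,
    batch_size: int = 64,
    lr: float = 1e-2,
) -> Tuple[PromoterPredictor, List[Dict[str, float]]]:
    """Minimize cross-entropy with Adam (lr 1e-2, betas (0.9, 0.999)).

    Training-mode dropout masks, shuffling, and initialization all derive
    from ``seed``, so a rerun reproduces the final weights bit-for-bit.
    Returns the predictor (updated in place) and a per-epoch history of
    loss and training accuracy.
    """
    X = _as_batch(X)
    labels = np.array([predictor.classes.index(c) for c in y])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain at least two classes")
    rng = nn.substream(seed, "predictor-train")
    cfg = predictor.cfg
    params = predictor.params
    opt = nn.Adam(params, lr=lr, betas=(0.9, 0.999))
    n = X.shape[0]
    l1 = cfg.seq_len // cfg.pool_window
    l2 = l1 // cfg.pool_window
    history: List[Dict[str, float]] = []

    def objective(p, xb, yb, masks):
        return nn.cross_entropy(predictor.apply(p, xb, masks), yb)

    gfun = grad(objective)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], labels[idx]
            masks = (
                nn.dropout_mask(rng, (len(idx), cfg.conv_channels[0], l1), cfg.dropout_p),
                nn.dropout_mask(rng, (len(idx), cfg.conv_channels[1], l2), cfg.dropout_p),
            )
            losses.append(float(objective(params, xb, yb, masks)))
            params = opt.step(params, gfun(params, xb, yb, masks))
        predictor.params = params
        pred = np.asarray(predictor.apply(params, X)).argmax(axis=1)
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": float(np.mean(pred == labels))}
        )
    return predictor, history


def filter_promoters(predictor, seqs) -> Tuple[list, list]:
    """Split sequences into (predicted promoters, rest), order-stable."""
    batch = _as_batch(list(seqs))
    preds = predictor.predict(batch)
    passed = [s for s, p in zip(seqs, preds) if p.is_promoter]
    rejected = [s for s, p in zip(seqs, preds) if not p.is_promoter]
    return passed, rejected


@dataclass
class CrossValidationResult:
    per_class_counts: Dict[str, ConfusionCounts]
    per_class_metrics: Dict[str, ClassifierMetrics]
    fold_accuracies: List[float]
    accuracy: float  # overall fraction correct, 0-1
    y_true: np.ndarray
    y_pred: np.ndarray


def cross_validate(
    builder: Callable[[], PromoterPredictor],
    X,
    y: Sequence[str],
    k: int = 10,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-2,
) -> CrossValidationResult:
    """Stratified k-fold CV; aggregates one-vs-rest confusion counts.

    ``builder`` must return a fresh untrained predictor per fold so folds
    are independent.  Deterministic given ``seed``.
    """
    X = _as_batch(X)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    smallest = min(int(np.sum(y == c)) for c in classes)
    if smallest < k:
        raise ValueError(f"smallest class has {smallest} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    y_pred = np.empty(len(y), dtype=object)
    fold_accs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        predictor = builder()
        train_predictor(
            predictor, X[tr], y[tr], epochs=epochs, seed=seed + 1000 + fold,
            batch_size=batch_size, lr=lr,
        )
        probs = predictor.predict_proba(X[te])
        pred = [predictor.classes[i] for i in probs.argmax(axis=1)]
        y_pred[te] = pred
        fold_accs.append(float(np.mean(np.asarray(pred) == y[te])))
    counts = {c: counts_from_predictions(y, y_pred, c) for c in classes}
    metrics = {c: classifier_metrics(counts[c]) for c in classes}
    return CrossValidationResult(
        per_class_counts=counts,
        per_class_metrics=metrics,
        fold_accuracies=fold_accs,
        accuracy=float(np.mean(y_pred == y)),
        y_true=y,
        y_pred=np.asarray(y_pred.tolist()),
    )
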