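"""Sequence containers, one-hot codec, FASTA/PWM I/O, and synthetic datasets.

The one-hot column order is (A, T, C, G) — A=(1,0,0,0), T=(0,1,0,0),
C=(0,0,1,0), G=(0,0,0,1) — and every array in the package uses it.  A
sequence of length L becomes an L×4 matrix whose rows are probability
distributions: exact indicators for hard sequences, softmax rows for
generator output.

The synthetic generators emulate the training data the pipeline needs:
background DNA with configurable composition, sequences with a PWM-sampled
motif embedded at a random offset, and a 4-class promoter task (background
plus three sigma-factor classes, each carrying a mutated class consensus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ATCG"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# complement swaps the (A,T) and (C,G) column pairs
COMPLEMENT_PERM = np.array([1, 0, 3, 2])

#: default class consensus motifs for the synthetic promoter task, loosely
#: modelled on the -35/-10 (sigma-24/32) and -24/-12 (sigma-54) elements of
#: bacterial sigma-factor binding sites.
DEFAULT_CLASS_MOTIFS: Dict[str, str] = {
    "sigma24": "GGAACTTTCTGAT",
    "sigma32": "CTTGAAACCCCAT",
    "sigma54": "TGGCACGGTTGCA",
}

PROMOTER_CLASSES = ("none", "sigma24", "sigma32", "sigma54")


class InvalidAlphabetError(ValueError):
    pass


class AmbiguousDecodeError(ValueError):
    pass


@dataclass
class NucleotideSequence:
    """A named DNA string over {A,C,G,T,N}."""

    id: str
    bases: str

    def __post_init__(self):
        self.bases = self.bases.upper()
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise InvalidAlphabetError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class OneHotSequence:
    """L×4 row-stochastic matrix over the (A,T,C,G) column order."""

    matrix: np.ndarray
    is_hard: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"one-hot matrix must be L x 4, got {m.shape}")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError("one-hot rows do not sum to 1 within tolerance")
        if np.any(np.abs(sums - 1.0) > 1e-6):
            m = m / sums[:, None]
        self.matrix = m
        if self.is_hard and not np.all((m == 0.0) | (m == 1.0)):
            raise ValueError("hard one-hot matrix contains non-binary entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PWM:
    """A Len×4 position weight matrix; each row is a distribution over (A,T,C,G)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM matrix must be Len x 4, got {m.shape}")
        if m.shape[0] < 1:
            raise ValueError("PWM must have at least one position")
        if np.any(m < 0):
            raise ValueError("PWM entries must be nonnegative")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError("PWM rows must sum to 1 within 1e-3")
        self.matrix = m / sums[:, None]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_achievable(self) -> float:
        """Best possible window inner product: sum of per-position column maxima."""
        return float(self.matrix.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


def pwm_from_consensus(consensus: str, p_max: float = 0.97, name: str = "consensus") -> PWM:
    """Sharp PWM putting probability ``p_max`` on each consensus base."""
    consensus = consensus.upper()
    rest = (1.0 - p_max) / 3.0
    m = np.full((len(consensus), 4), rest)
    for j, b in enumerate(consensus):
        m[j, BASE_INDEX[b]] = p_max
    return PWM(name=name, matrix=m)


# ---------------------------------------------------------------------------
# one-hot codec


def one_hot_encode(seq: NucleotideSequence, n_policy: str = "reject") -> OneHotSequence:
    """Encode a sequence as an L×4 matrix, A=(1,0,0,0) T=(0,1,0,0) C=(0,0,1,0) G=(0,0,0,1).

    ``n_policy='uniform'`` maps N to (0.25, 0.25, 0.25, 0.25); ``'reject'``
    raises on any N.
    """
    if n_policy not in ("reject", "uniform"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    has_n = "N" in seq.bases
    if has_n and n_policy == "reject":
        raise InvalidAlphabetError(f"sequence {seq.id!r} contains N under reject policy")
    m = np.zeros((len(seq), 4))
    for i, b in enumerate(seq.bases):
        if b == "N":
            m[i, :] = 0.25
        else:
            m[i, BASE_INDEX[b]] = 1.0
    return OneHotSequence(matrix=m, is_hard=not has_n)


def one_hot_decode(
    oh: OneHotSequence, tie_break: str = "first", id: str = "seq"
) -> NucleotideSequence:
    """Per-row argmax back to bases; ties go to the first base in (A,T,C,G) order."""
    if tie_break not in ("first", "error"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    m = oh.matrix
    if tie_break == "error":
        row_max = m.max(axis=1)
        if np.any((m == row_max[:, None]).sum(axis=1) > 1):
            raise AmbiguousDecodeError("tied row maxima during decode")
    return NucleotideSequence(id=id, bases="".join(ALPHABET[i] for i in m.argmax(axis=1)))


def encode_batch(seqs: Sequence[NucleotideSequence], n_policy: str = "reject") -> np.ndarray:
    """Stack equal-length sequences into a (B, L, 4) hard one-hot array."""
    if not seqs:
        return np.zeros((0, 0, 4))
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have ragged lengths {sorted(lengths)}")
    return np.stack([one_hot_encode(s, n_policy).matrix for s in seqs])


def decode_batch(arr: np.ndarray, prefix: str = "gen") -> List[NucleotideSequence]:
    return [
        one_hot_decode(OneHotSequence(matrix=row), id=f"{prefix}_{i}")
        for i, row in enumerate(np.asarray(arr))
    ]


def hard_argmax(arr: np.ndarray) -> np.ndarray:
    """Row-wise argmax of a (B, L, 4) soft batch as a (B, L, 4) hard batch."""
    arr = np.asarray(arr)
    idx = arr.argmax(axis=2)
    hard = np.zeros_like(arr)
    b, l = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij")
    hard[b, l, idx] = 1.0
    return hard


# ---------------------------------------------------------------------------
# FASTA / PWM / label-table I/O


def read_fasta(path) -> List[NucleotideSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    return [NucleotideSequence(id=r.id, bases=str(r.seq).upper()) for r in records]


def write_fasta(seqs: Sequence[NucleotideSequence], path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path) -> Dict[str, str]:
    """Two-column tab-separated id→label table."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, label = line.split("\t")
            labels[sid] = label
    return labels


def write_labels(pairs, path) -> None:
    with open(path, "w") as fh:
        for sid, label in pairs:
            fh.write(f"{sid}\t{label}\n")


def read_pwm(path, orientation: Optional[str] = None) -> PWM:
    """Read a whitespace-separated PWM matrix.

    Accepts both the Len×4 layout (one row per motif position) and the
    transposed 4×Len dialect; orientation is auto-detected by which axis has
    size 4.  A 4×4 matrix is ambiguous and requires ``orientation`` of
    ``'positions'`` (rows are positions) or ``'bases'`` (rows are bases).
    """
    name = "pwm"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                comment = line.lstrip("#").strip()
                if comment and name == "pwm":
                    name = comment
                continue
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"empty PWM file {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("ragged rows in PWM file")
    m = np.array(rows)
    if m.shape == (4, 4):
        if orientation is None:
            raise ValueError("4x4 PWM is ambiguous; pass orientation='positions' or 'bases'")
        if orientation == "bases":
            m = m.T
    elif m.shape[1] == 4:
        pass
    elif m.shape[0] == 4:
        m = m.T
    else:
        raise ValueError(f"cannot interpret PWM of shape {m.shape}: no axis has size 4")
    return PWM(name=name, matrix=m)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {pwm.name}\n")
        for row in pwm.matrix:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# synthetic datasets


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a simulated sequence set.

    With ``motif`` set, each sequence independently carries one motif
    instance (sampled per position from the PWM) at a uniform random offset
    with probability ``motif_embed_prob``.  With ``class_motifs`` set, labels
    are balanced over {none} ∪ classes and each non-background class embeds
    its consensus with per-base mutation rate ``class_mutation_rate``.
    """

    n_sequences: int
    length: int
    background_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: Optional[PWM] = None
    motif_embed_prob: float = 0.0
    class_motifs: Optional[Dict[str, str]] = None
    class_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.background_freqs, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        if not (0.0 <= self.motif_embed_prob <= 1.0):
            raise ValueError("motif_embed_prob must be in [0, 1]")
        if self.motif is not None and self.motif.length > self.length:
            raise ValueError("motif longer than sequence length")
        if self.class_motifs is not None:
            for label, cons in self.class_motifs.items():
                if len(cons) > self.length:
                    raise ValueError(f"class motif for {label!r} longer than sequence length")


@dataclass
class SimulatedDataset:
    sequences: List[NucleotideSequence]
    labels: Optional[List[str]] = None
    #: True where a PWM motif instance was embedded (motif mode only)
    embedded: Optional[List[bool]] = None

    def __len__(self):
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]


def _random_bases(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=freqs)


def _mutate(rng: np.random.Generator, idx: np.ndarray, rate: float) -> np.ndarray:
    out = idx.copy()
    hits = rng.random(len(idx)) < rate
    for i in np.nonzero(hits)[0]:
        choices = [b for b in range(4) if b != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_dataset(spec: SyntheticDatasetSpec) -> SimulatedDataset:
    """Generate sequences per the spec; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.background_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    L = spec.length

    if spec.class_motifs is not None:
        class_labels = ["none"] + sorted(spec.class_motifs)
        n_cls = len(class_labels)
        labels = [class_labels[i % n_cls] for i in range(spec.n_sequences)]
        rng.shuffle(labels)
        seqs = []
        for i, label in enumerate(labels):
            idx = _random_bases(rng, L, freqs)
            if label != "none":
                cons = spec.class_motifs[label].upper()
                motif_idx = np.array([BASE_INDEX[b] for b in cons])
                motif_idx = _mutate(rng, motif_idx, spec.class_mutation_rate)
                off = int(rng.integers(0, L - len(cons) + 1))
                idx[off : off + len(cons)] = motif_idx
            seqs.append(
                NucleotideSequence(id=f"sim_{i}_{label}", bases="".join(ALPHABET[b] for b in idx))
            )
        return SimulatedDataset(sequences=seqs, labels=labels)

    seqs = []
    embedded: Optional[List[bool]] = None
    if spec.motif is not None:
        embedded = []
    for i in range(spec.n_sequences):
        idx = _random_bases(rng, L, freqs)
        if spec.motif is not None:
            embed = bool(rng.random() < spec.motif_embed_prob)
            embedded.append(embed)
            if embed:
                pm = spec.motif.matrix
                inst = np.array([rng.choice(4, p=pm[j]) for j in range(spec.motif.length)])
                off = int(rng.integers(0, L - spec.motif.length + 1))
                idx[off : off + spec.motif.length] = inst
        seqs.append(NucleotideSequence(id=f"sim_{i}", bases="".join(ALPHABET[b] for b in idx)))
    return SimulatedDataset(sequences=seqs, embedded=embedded)
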