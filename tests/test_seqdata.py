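"""Sequence types, one-hot codec, file I/O, and the synthetic generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqforge import seqdata
from seqforge.motif_evaluator import motif_score
from seqforge.seqdata import (
    InvalidAlphabetError,
    NucleotideSequence,
    OneHotSequence,
    SyntheticDatasetSpec,
    one_hot_decode,
    one_hot_encode,
    pwm_from_consensus,
    read_fasta,
    read_pwm,
    simulate_dataset,
    write_fasta,
    write_pwm,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestOneHotCodec:
    @pytest.mark.parametrize(
        "base,vec",
        [("A", [1, 0, 0, 0]), ("T", [0, 1, 0, 0]), ("C", [0, 0, 1, 0]), ("G", [0, 0, 0, 1])],
    )
    def test_single_base_vectors(self, base, vec):
        oh = one_hot_encode(NucleotideSequence("s", base))
        assert oh.matrix.tolist() == [vec]
        assert oh.is_hard

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna)
    def test_round_trip_identity(self, bases):
        s = NucleotideSequence("s", bases)
        assert one_hot_decode(one_hot_encode(s)).bases == bases

    def test_one_one_per_row(self):
        m = one_hot_encode(NucleotideSequence("s", "ACGT")).matrix
        assert m.shape == (4, 4)
        assert np.all(m.sum(axis=1) == 1)
        assert np.all((m == 0) | (m == 1))

    def test_n_policies(self):
        s = NucleotideSequence("s", "ANT")
        with pytest.raises(InvalidAlphabetError):
            one_hot_encode(s, n_policy="reject")
        oh = one_hot_encode(s, n_policy="uniform")
        assert np.allclose(oh.matrix[1], 0.25)
        assert not oh.is_hard

    def test_decode_argmax_and_ties(self):
        soft = OneHotSequence(matrix=np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert one_hot_decode(soft).bases == "A"
        tie = OneHotSequence(matrix=np.full((1, 4), 0.25))
        assert one_hot_decode(tie, tie_break="first").bases == "A"
        with pytest.raises(seqdata.AmbiguousDecodeError):
            one_hot_decode(tie, tie_break="error")

    def test_row_sum_validation(self):
        with pytest.raises(ValueError):
            OneHotSequence(matrix=np.array([[0.5, 0.1, 0.1, 0.1]]))
        # within 1e-3 of 1 -> renormalized
        oh = OneHotSequence(matrix=np.array([[0.5004, 0.4996, 0.0, 0.0004]]))
        assert np.allclose(oh.matrix.sum(axis=1), 1.0, atol=1e-9)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        seqs = [
            NucleotideSequence("a", "ACGTACGT"),
            NucleotideSequence("b", "TTTT"),
            NucleotideSequence("c", "G" * 130),
        ]
        path = tmp_path / "x.fasta"
        write_fasta(seqs, path)
        back = read_fasta(path)
        assert [(s.id, s.bases) for s in back] == [(s.id, s.bases) for s in seqs]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">s\nacgt\n")
        assert read_fasta(path)[0].bases == "ACGT"


class TestPwmIO:
    def test_uniform_rows(self, tmp_path):
        path = tmp_path / "u.pwm"
        path.write_text("# uniform\n" + "0.25 0.25 0.25 0.25\n" * 3)
        pwm = read_pwm(path)
        assert pwm.length == 3
        assert np.allclose(pwm.matrix, 0.25)
        assert pwm.name == "uniform"

    def test_unnormalizable_row_rejected(self, tmp_path):
        path = tmp_path / "bad.pwm"
        path.write_text("2 0 0 0\n")
        with pytest.raises(ValueError):
            read_pwm(path)

    def test_tolerant_renormalization(self, tmp_path):
        path = tmp_path / "t.pwm"
        path.write_text("0.5004 0.4996 0 0\n0.25 0.25 0.25 0.25\n")
        pwm = read_pwm(path)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_transposed_dialect_autodetected(self, tmp_path):
        pwm = pwm_from_consensus("TATAA")
        path = tmp_path / "trans.pwm"
        with open(path, "w") as fh:
            for row in pwm.matrix.T:  # 4 rows x Len columns
                fh.write(" ".join(map(str, row)) + "\n")
        back = read_pwm(path)
        assert np.allclose(back.matrix, pwm.matrix)

    def test_square_requires_orientation(self, tmp_path):
        pwm = pwm_from_consensus("ACGT")
        path = tmp_path / "sq.pwm"
        write_pwm(pwm, path)
        with pytest.raises(ValueError):
            read_pwm(path)
        back = read_pwm(path, orientation="positions")
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-6)

    def test_write_read_round_trip(self, tmp_path, tata_pwm):
        path = tmp_path / "rt.pwm"
        write_pwm(tata_pwm, path)
        back = read_pwm(path)
        assert np.allclose(back.matrix, tata_pwm.matrix, atol=1e-5)


class TestSimulateDataset:
    def test_deterministic_given_seed(self):
        spec = SyntheticDatasetSpec(n_sequences=100, length=50, seed=1)
        a = simulate_dataset(spec)
        b = simulate_dataset(spec)
        assert [s.bases for s in a] == [s.bases for s in b]

    def test_embedded_motif_scores_high(self, tata_pwm):
        spec = SyntheticDatasetSpec(
            n_sequences=200, length=50, motif=tata_pwm, motif_embed_prob=1.0, seed=2
        )
        ds = simulate_dataset(spec)
        # brute-force window scan over the generated set.  Instances are
        # sampled per position from the PWM, so with column max 0.97 over 6
        # positions a window passes 0.8 whenever at most one position missed
        # the consensus: P(k<=1) for k ~ Binomial(6, 0.03) is 0.998.
        n_hit = 0
        for s in ds:
            oh = one_hot_encode(s).matrix
            best = max(
                sum(tata_pwm.matrix[j, oh[o + j].argmax()] for j in range(tata_pwm.length))
                for o in range(len(s) - tata_pwm.length + 1)
            )
            if best / tata_pwm.max_achievable > 0.8:
                n_hit += 1
        assert n_hit / len(ds) >= 0.95
        assert all(ds.embedded)

    def test_background_kmer_distribution(self):
        from scipy.stats import chisquare

        spec = SyntheticDatasetSpec(n_sequences=5000, length=20, seed=3)
        ds = simulate_dataset(spec)
        counts = np.zeros(256)
        for s in ds:
            b = s.bases
            for i in range(len(b) - 3):
                idx = 0
                for ch in b[i : i + 4]:
                    idx = idx * 4 + seqdata.BASE_INDEX[ch]
                counts[idx] += 1
        # non-overlapping would be cleaner; overlap inflates variance only mildly
        stat, p = chisquare(counts)
        assert p > 0.001

    def test_background_base_frequencies_converge(self):
        freqs = (0.4, 0.3, 0.2, 0.1)
        spec = SyntheticDatasetSpec(n_sequences=2000, length=50, background_freqs=freqs, seed=4)
        ds = simulate_dataset(spec)
        counts = np.zeros(4)
        for s in ds:
            for b in s.bases:
                counts[seqdata.BASE_INDEX[b]] += 1
        n = counts.sum()
        for i, f in enumerate(freqs):
            se = np.sqrt(f * (1 - f) / n)
            assert abs(counts[i] / n - f) < 3 * se

    def test_class_dataset_balanced_and_learnable_signal(self):
        spec = SyntheticDatasetSpec(
            n_sequences=200, length=60, class_motifs=seqdata.DEFAULT_CLASS_MOTIFS, seed=5
        )
        ds = simulate_dataset(spec)
        counts = {c: ds.labels.count(c) for c in set(ds.labels)}
        assert max(counts.values()) - min(counts.values()) <= 1
        # nearly all labeled sequences score high for their own class motif;
        # the 0.05 per-base mutation rate leaves a small Binomial(13, 0.05)
        # tail of heavily mutated instances, so assert on the 95% mass
        scores = []
        for s, label in zip(ds.sequences, ds.labels):
            if label == "none":
                continue
            pwm = pwm_from_consensus(seqdata.DEFAULT_CLASS_MOTIFS[label])
            scores.append(motif_score(one_hot_encode(s), pwm).normalized)
        assert np.mean(np.asarray(scores) > 0.75) >= 0.95

    def test_motif_longer_than_sequence_rejected(self, tata_pwm):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(n_sequences=1, length=3, motif=tata_pwm, motif_embed_prob=1.0)
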