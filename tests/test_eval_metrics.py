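"""Fidelity metrics, Fréchet DP vs recursive oracle, classifier metrics."""

import numpy as np
import pytest
from scipy import stats

from seqforge import eval_metrics as em
from seqforge.eval_metrics import (
    ConfusionCounts,
    build_feature_matrix,
    classifier_metrics,
    compare_datasets,
    counts_from_predictions,
    frechet_distance,
    mae,
    mirror_column_association,
    pearson,
    prd,
    rmse,
    roc_curve,
)
from seqforge.seqdata import NucleotideSequence, SyntheticDatasetSpec, simulate_dataset


def frechet_oracle(O, P):
    """Exponential memoized recursion straight from the coupling definition."""
    from functools import lru_cache

    O = np.atleast_2d(O)
    P = np.atleast_2d(P)

    @lru_cache(maxsize=None)
    def c(i, j):
        d = float(np.linalg.norm(O[i] - P[j]))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d)

    return c(len(O) - 1, len(P) - 1)


class TestFeatureMatrix:
    def test_single_sequence_position_freq(self):
        fm = build_feature_matrix([NucleotideSequence("s", "AAAA")], mode="position_freq")
        assert fm.matrix.shape == (4, 4)
        assert np.allclose(fm.matrix[0], 1.0)  # A row
        assert np.allclose(fm.matrix.sum(axis=0), 1.0)

    def test_kmer_k1_uniform(self):
        fm = build_feature_matrix([NucleotideSequence("s", "ACGT")], mode="kmer_freq", k=1)
        assert fm.matrix.shape == (4, 1)
        assert np.allclose(fm.matrix, 0.25)

    def test_ragged_lengths_rejected(self):
        seqs = [NucleotideSequence("a", "ACGT"), NucleotideSequence("b", "ACG")]
        with pytest.raises(ValueError):
            build_feature_matrix(seqs, mode="position_freq")


class TestElementwiseStats:
    def test_identity_pairs(self, rng):
        x = rng.random(20)
        assert pearson(x, x) == pytest.approx(1.0)
        assert mae(x, x) == 0.0
        assert prd(x, x) == 0.0
        assert rmse(x, x) == 0.0

    def test_anticorrelation(self, rng):
        x = rng.random(20)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_scipy(self):
        Or = np.array([1.0, 2.0, 3.0, 4.0])
        Sn = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson(Or, Sn) == pytest.approx(stats.pearsonr(Or, Sn).statistic, abs=1e-12)

    def test_pearson_affine_invariance(self, rng):
        x, y = rng.random(15), rng.random(15)
        assert pearson(2.5 * x + 1.0, y) == pytest.approx(pearson(x, y), abs=1e-10)

    def test_pearson_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_constant_offset(self, rng):
        x = rng.random(10)
        assert mae(x, x + 0.3) == pytest.approx(0.3)
        assert rmse(x, x + 0.3) == pytest.approx(0.3)

    def test_prd_zero_synthetic_is_100(self, rng):
        x = rng.random(10)
        assert prd(x, np.zeros(10)) == pytest.approx(100.0)

    def test_elementwise_against_loop_oracle(self, rng):
        Or, Sn = rng.random(30), rng.random(30)
        assert mae(Or, Sn) == pytest.approx(sum(abs(a - b) for a, b in zip(Or, Sn)) / 30, abs=1e-12)
        assert rmse(Or, Sn) == pytest.approx(
            np.sqrt(sum((a - b) ** 2 for a, b in zip(Or, Sn)) / 30), abs=1e-12
        )
        assert prd(Or, Sn) == pytest.approx(
            100 * np.sqrt(sum((a - b) ** 2 for a, b in zip(Or, Sn)) / sum(a**2 for a in Or)),
            abs=1e-9,
        )

    def test_distance_metrics_symmetry(self, rng):
        Or, Sn = rng.random(12), rng.random(12)
        assert mae(Or, Sn) == mae(Sn, Or)
        assert rmse(Or, Sn) == rmse(Sn, Or)
        assert prd(Or, Sn) != prd(Sn, Or)  # normalized by the original only


class TestMirrorColumnAssociation:
    def make_fm(self, m):
        return em.FeatureMatrix(matrix=m, column_labels=[str(j) for j in range(m.shape[1])],
                                provenance="position_freq")

    def test_identity_is_one(self, rng):
        m = rng.random((4, 6))
        fm = self.make_fm(m)
        res = mirror_column_association(fm, fm)
        assert res.association == pytest.approx(1.0)
        assert res.n_skipped == 0

    def test_single_column_equals_pearson(self, rng):
        a, b = rng.random((4, 1)), rng.random((4, 1))
        res = mirror_column_association(self.make_fm(a), self.make_fm(b))
        assert res.association == pytest.approx(pearson(a[:, 0], b[:, 0]))

    def test_two_columns_hand_average(self, rng):
        a, b = rng.random((4, 2)), rng.random((4, 2))
        res = mirror_column_association(self.make_fm(a), self.make_fm(b))
        expected = 0.5 * (pearson(a[:, 0], b[:, 0]) + pearson(a[:, 1], b[:, 1]))
        assert res.association == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_columns_skipped(self, rng):
        a = rng.random((4, 3))
        a[:, 1] = 0.25
        b = rng.random((4, 3))
        res = mirror_column_association(self.make_fm(a), self.make_fm(b))
        assert res.n_skipped == 1

    def test_all_constant_errors(self):
        a = np.full((4, 2), 0.25)
        with pytest.raises(ValueError):
            mirror_column_association(self.make_fm(a), self.make_fm(a))


class TestFrechet:
    def test_identical_curves_zero(self, rng):
        c = rng.random((6, 3))
        assert frechet_distance(c, c) == 0.0

    def test_single_points(self):
        a, d = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert frechet_distance(a, d) == pytest.approx(5.0)

    def test_matches_recursive_oracle(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            O, P = rng.random((n, 2)), rng.random((m, 2))
            assert frechet_distance(O, P) == pytest.approx(frechet_oracle(O, P), abs=1e-12)

    def test_start_point_lower_bound(self, rng):
        O, P = rng.random((5, 2)), rng.random((5, 2))
        assert frechet_distance(O, P) >= np.linalg.norm(O[0] - P[0]) - 1e-12

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(np.zeros((0, 2)), np.zeros((3, 2)))


class TestClassifierMetrics:
    def test_perfect_classifier(self):
        m = classifier_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert m == pytest.approx((100.0, 1.0, 100.0, 100.0))

    def test_total_disagreement(self):
        m = classifier_metrics(ConfusionCounts(TP=0, TN=0, FP=10, FN=10))
        assert m.acc == 0.0
        assert m.mcc == pytest.approx(-1.0)

    def test_matches_counting_oracle(self, rng):
        y_true = rng.choice(["pos", "neg"], size=500)
        y_pred = rng.choice(["pos", "neg"], size=500)
        c = counts_from_predictions(y_true, y_pred, positive="pos")
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == "pos" and p == "pos")
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == "neg" and p == "neg")
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == "neg" and p == "pos")
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == "pos" and p == "neg")
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert c.total == 500
        m = classifier_metrics(c)
        assert m.acc == pytest.approx(100 * (tp + tn) / 500)
        assert m.sen == pytest.approx(100 * tp / (tp + fn))
        assert m.spc == pytest.approx(100 * tn / (tn + fp))

    def test_mcc_zero_denominator_convention(self):
        # classifier that never predicts positive: TP+FP = 0
        m = classifier_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=5))
        assert m.mcc == 0.0

    def test_undefined_sen_spc_raise(self):
        with pytest.raises(ValueError):
            classifier_metrics(ConfusionCounts(TP=0, TN=5, FP=5, FN=0))
        with pytest.raises(ValueError):
            classifier_metrics(ConfusionCounts(TP=5, TN=0, FP=0, FN=5))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_reversal_symmetry(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        _, auc = roc_curve(scores, labels)
        _, auc_rev = roc_curve(-scores, labels)
        assert auc_rev == pytest.approx(1.0 - auc, abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.03


class TestCompareDatasets:
    def test_identity_comparison(self, background_seqs):
        r = compare_datasets(background_seqs, background_seqs)
        assert r.pearson == pytest.approx(1.0)
        assert r.mae == 0.0
        assert r.prd == 0.0
        assert r.rmse == 0.0
        assert r.mirror_column_association == pytest.approx(1.0)
        assert r.frechet == 0.0

    def test_disjoint_compositions(self):
        orig = [NucleotideSequence(f"a{i}", "A" * 10) for i in range(3)]
        syn = [NucleotideSequence(f"t{i}", "T" * 10) for i in range(3)]
        r = compare_datasets(orig, syn)
        assert r.mae > 0
        # per-position profiles are (1,0,0,0) vs (0,1,0,0): association -1/3
        assert r.mirror_column_association == pytest.approx(-1 / 3, abs=1e-9)
        assert r.frechet == pytest.approx(np.sqrt(2.0))

    def test_finite_on_random_sets(self):
        a = simulate_dataset(SyntheticDatasetSpec(n_sequences=30, length=20, seed=1)).sequences
        b = simulate_dataset(SyntheticDatasetSpec(n_sequences=40, length=20, seed=2)).sequences
        for mode in ("position_freq", "kmer_freq"):
            r = compare_datasets(a, b, mode=mode, k=2)
            assert all(np.isfinite(v) for v in r.as_dict().values())
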