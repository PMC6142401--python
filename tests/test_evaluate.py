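"""Differential testing, clustering metrics, classification harness."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

from fcmodules import (binary_metrics, cluster_eval, cophenetic_correlation,
                       de_fc_test, maxvote_classify, mcnemar_compare,
                       subsample_experiment)


class TestDEFCTest:
    def test_null_no_discoveries(self, rng):
        base = rng.normal(size=(10, 8))
        scores = np.hstack([base, base + 1e-9 * rng.normal(size=(10, 8))])
        groups = ["A"] * 8 + ["B"] * 8
        table = de_fc_test(scores, groups, alpha=0.05)
        assert table["de"].sum() == 0

    def test_planted_shift_detected(self):
        detected, false_pos = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=(10, 20))
            scores[3, 10:] += 5.0  # 5-SD shift on one component
            table = de_fc_test(scores, ["A"] * 10 + ["B"] * 10, alpha=0.05)
            detected += bool(table.loc[3, "de"])
            false_pos += int(table["de"].sum()) - bool(table.loc[3, "de"])
        assert detected == 20
        assert false_pos / (20 * 9) <= 0.05

    def test_family_size_inflates_adjustment(self, rng):
        scores = rng.normal(size=(5, 12))
        groups = ["A"] * 6 + ["B"] * 6
        small = de_fc_test(scores, groups, family_size=5)
        large = de_fc_test(scores, groups, family_size=100)
        assert (large["p_adj"] >= small["p_adj"] - 1e-12).all()

    def test_group_size_validation(self, rng):
        with pytest.raises(ValueError):
            de_fc_test(rng.normal(size=(3, 3)), ["A", "A", "B"])


class TestClusterEval:
    def test_perfect_split(self):
        res = cluster_eval([1] * 5 + [2] * 5, ["A"] * 5 + ["B"] * 5)
        assert res.purity == 1.0
        assert all(g == 0.0 for g in res.gini.values())

    def test_worked_example(self):
        # clusters (9A+1B) and (2A+8B): purity 17/20, Gini 0.18 and 0.32
        assign = [1] * 10 + [2] * 10
        labels = ["A"] * 9 + ["B"] + ["A"] * 2 + ["B"] * 8
        res = cluster_eval(assign, labels)
        assert res.purity == pytest.approx(0.85)
        assert res.gini[1] == pytest.approx(0.18)
        assert res.gini[2] == pytest.approx(0.32)
        assert res.assignment == {1: "A", 2: "B"}

    def test_single_balanced_cluster(self):
        res = cluster_eval([1] * 20, ["A"] * 10 + ["B"] * 10)
        assert res.purity == 0.5
        assert res.gini[1] == pytest.approx(0.5)
        assert res.tied_clusters == [1]
        assert res.assignment[1] == "A"  # tie goes to the lower-indexed class

    def test_purity_invariant_to_cluster_relabeling(self, rng):
        assign = rng.integers(0, 3, size=30)
        labels = rng.choice(["A", "B"], size=30)
        res1 = cluster_eval(assign, labels)
        res2 = cluster_eval(10 - assign, labels)
        assert res1.purity == res2.purity


class TestCopheneticCorrelation:
    def test_identical_trees(self, rng):
        X = rng.normal(size=(8, 4))
        Z = hierarchy.linkage(X, method="average")
        assert cophenetic_correlation(Z, Z) == pytest.approx(1.0)

    def test_same_distances_same_linkage(self, rng):
        X = rng.normal(size=(10, 3))
        Z1 = hierarchy.linkage(X, method="average")
        Z2 = hierarchy.linkage(X.copy(), method="average")
        assert cophenetic_correlation(Z1, Z2) == pytest.approx(1.0)

    def test_four_leaf_hand_example(self):
        # tree 1: (a,b)@1, (c,d)@2, join@4 ; tree 2: (a,c)@1, (b,d)@2, join@4
        z1 = np.array([[0, 1, 1.0, 2], [2, 3, 2.0, 2], [4, 5, 4.0, 4]])
        z2 = np.array([[0, 2, 1.0, 2], [1, 3, 2.0, 2], [4, 5, 4.0, 4]])
        # cophenetic vectors over pairs (ab, ac, ad, bc, bd, cd)
        d1 = np.array([1, 4, 4, 4, 4, 2.0])
        d2 = np.array([4, 1, 4, 4, 2, 4.0])
        expected = np.corrcoef(d1, d2)[0, 1]
        assert cophenetic_correlation(z1, z2) == pytest.approx(expected)

    def test_mismatched_leaves_error(self):
        z1 = np.array([[0, 1, 1.0, 2]])
        z2 = np.array([[0, 1, 1.0, 2], [2, 3, 2.0, 2], [4, 5, 4.0, 4]])
        with pytest.raises(ValueError):
            cophenetic_correlation(z1, z2)


class TestMaxVote:
    def separable_data(self, rng, k=3, per_class=30, dim=5):
        X, y = [], []
        for c in range(k):
            center = np.zeros(dim)
            center[c] = 8.0
            X.append(center + rng.normal(size=(per_class, dim)))
            y += [f"C{c+1}"] * per_class
        return np.vstack(X), y

    def test_two_class_no_ties_possible(self, rng):
        X, y = self.separable_data(rng, k=2)
        cm = maxvote_classify(X, y, folds=5, runs=2, seed=0)
        np.testing.assert_allclose(cm.idc, 0.0)
        np.testing.assert_allclose(cm.call_rate, 1.0)

    def test_separable_three_class_perfect_sensitivity(self, rng):
        X, y = self.separable_data(rng, k=3)
        cm = maxvote_classify(X, y, folds=5, runs=2, seed=0)
        np.testing.assert_allclose(cm.sensitivity, 1.0)
        np.testing.assert_allclose(cm.counts.sum(axis=1) + cm.idc, cm.totals)

    def test_sensitivity_uses_called_denominator(self, rng):
        X, y = self.separable_data(rng, k=3, per_class=12)
        cm = maxvote_classify(X, y, folds=4, runs=1, seed=1)
        called = cm.counts.sum(axis=1)
        expected = np.diag(cm.counts) / called
        np.testing.assert_allclose(cm.sensitivity, expected)

    def test_single_class_error(self, rng):
        with pytest.raises(ValueError):
            maxvote_classify(rng.normal(size=(10, 2)), ["A"] * 10)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        rec = binary_metrics(["P"] * 5 + ["N"] * 10, ["P"] * 5 + ["N"] * 10, "P")
        assert (rec.PPV, rec.NPV, rec.sensitivity, rec.specificity,
                rec.accuracy) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_worked_confusion_counts(self):
        # TP=3, FP=1, FN=2, TN=4
        truth = ["P"] * 5 + ["N"] * 5
        pred = ["P", "P", "P", "N", "N", "P", "N", "N", "N", "N"]
        rec = binary_metrics(pred, truth, "P")
        assert (rec.TP, rec.FP, rec.FN, rec.TN) == (3, 1, 2, 4)
        assert rec.PPV == pytest.approx(0.75)
        assert rec.NPV == pytest.approx(2 / 3)
        assert rec.sensitivity == pytest.approx(0.6)
        assert rec.specificity == pytest.approx(0.8)
        assert rec.accuracy == pytest.approx(0.7)
        assert rec.TP + rec.FN == rec.P and rec.TN + rec.FP == rec.N

    def test_all_negative_predictor_undefined_ppv(self):
        truth = ["P"] * 3 + ["N"] * 7
        rec = binary_metrics(["N"] * 10, truth, "P")
        assert rec.PPV is None
        assert rec.specificity == 1.0
        assert rec.sensitivity == 0.0

    def test_accuracy_convex_combination(self, rng):
        truth = rng.choice(["P", "N"], size=50, p=[0.3, 0.7])
        pred = rng.choice(["P", "N"], size=50)
        rec = binary_metrics(pred, truth, "P")
        prev = rec.P / (rec.P + rec.N)
        assert rec.accuracy == pytest.approx(
            prev * rec.sensitivity + (1 - prev) * rec.specificity)


class TestMcNemar:
    def test_discordant_10_2(self):
        # b=10, c=2: statistic (|10-2|-1)^2 / 12 = 49/12
        truth = np.zeros(12, dtype=int)
        pred_a = np.zeros(12, dtype=int)
        pred_b = np.ones(12, dtype=int)
        pred_a[10:] = 1  # a wrong on last 2
        pred_b[10:] = 0  # b right exactly there
        stat, p, verdict = mcnemar_compare(pred_a, pred_b, truth)
        assert stat == pytest.approx(49 / 12)
        assert p < 0.05 and verdict == "different"

    def test_balanced_discordance(self):
        truth = np.zeros(10, dtype=int)
        pred_a = np.array([0] * 5 + [1] * 5)
        pred_b = np.array([1] * 5 + [0] * 5)
        stat, p, verdict = mcnemar_compare(pred_a, pred_b, truth)
        assert stat == pytest.approx(0.1)
        assert verdict == "not_different"

    def test_identical_predictions(self):
        pred = np.array([0, 1, 0])
        stat, p, verdict = mcnemar_compare(pred, pred, np.array([0, 0, 1]))
        assert verdict == "identical" and stat is None

    def test_symmetric_in_b_and_c(self, rng):
        truth = rng.integers(0, 2, 30)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        s1, _, _ = mcnemar_compare(a, b, truth)
        s2, _, _ = mcnemar_compare(b, a, truth)
        assert s1 == pytest.approx(s2)


class TestSubsampleExperiment:
    def make_two_space_data(self, rng, n_pos=40, n_neg=60, dim=6):
        y = np.array(["C3"] * n_pos + ["C8"] * n_neg)
        signal = (y == "C3").astype(float)[:, None]
        fc = signal * 2.0 + rng.normal(size=(y.size, dim))
        gene = np.hstack([fc + rng.normal(size=fc.shape),
                          rng.normal(size=(y.size, 40))])
        return {"fc": fc, "gene": gene}, y

    def test_table_shape_and_training_pools(self, rng):
        spaces, y = self.make_two_space_data(rng)
        table = subsample_experiment(
            spaces, y, "C3", "C8", test_sizes=(8, 12),
            fractions=(0.2, 1.0), repeats=3, runs=2, seed=0)
        assert set(table["space"]) == {"fc", "gene", "both"}
        assert set(table["fraction"]) == {0.2, 1.0}
        ppv_rows = table[(table.metric == "PPV") & (table.space == "fc")]
        assert len(ppv_rows) == 2
        assert table["mean"].between(-1e-9, 100.0).all()

    def test_bit_reproducible_with_fixed_seed(self, rng):
        spaces, y = self.make_two_space_data(rng)
        kwargs = dict(test_sizes=(8, 12), fractions=(0.4,), repeats=2,
                      runs=2, seed=3)
        t1 = subsample_experiment(spaces, y, "C3", "C8", **kwargs)
        t2 = subsample_experiment(spaces, y, "C3", "C8", **kwargs)
        import pandas as pd

        pd.testing.assert_frame_equal(t1, t2)

    def test_pool_too_small_error(self, rng):
        spaces, y = self.make_two_space_data(rng, n_pos=5, n_neg=5)
        with pytest.raises(ValueError):
            subsample_experiment(spaces, y, "C3", "C8", test_sizes=(5, 3),
                                 repeats=1, runs=1)
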