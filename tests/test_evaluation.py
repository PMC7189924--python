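"""Splitting, joint accuracy, outcome association, model comparison."""

import numpy as np
import pytest

from bivbin.dataset import BivariateBinaryDataset
from bivbin.evaluation import (
    SplitSpec,
    association_chi2,
    compare_models,
    default_models,
    joint_accuracy,
    marginal_accuracy,
    split,
)
from bivbin.simulate import mi_cohort_fixture


class TestSplit:
    def test_cohort_sizes_70_30(self):
        data = mi_cohort_fixture(seed=0)
        train, test = split(data, SplitSpec(train_fraction=0.7, seed=1))
        assert (train.n, test.n) == (184, 79)

    def test_same_seed_same_membership(self):
        data = mi_cohort_fixture(seed=2)
        a = split(data, SplitSpec(seed=9))
        b = split(data, SplitSpec(seed=9))
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y2, b[1].y2)

    @pytest.mark.parametrize("stratify", [True, False])
    def test_disjoint_exhaustive_half_split(self, stratify):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 1))
        data = BivariateBinaryDataset(X, rng.integers(0, 2, 10), rng.integers(0, 2, 10))
        train, test = split(data, SplitSpec(train_fraction=0.5, seed=4,
                                            stratify=stratify))
        assert train.n == test.n == 5
        merged = np.sort(np.r_[train.X[:, 0], test.X[:, 0]])
        np.testing.assert_array_equal(merged, np.sort(X[:, 0]))

    def test_stratified_keeps_rare_cells_in_both_parts(self):
        data = mi_cohort_fixture(seed=3)
        train, test = split(data, SplitSpec(seed=5, stratify=True))
        # deaths (~8%) must not be flushed entirely into one part
        assert train.y2.sum() > 0 and test.y2.sum() > 0

    def test_empty_part_rejected(self):
        data = mi_cohort_fixture(seed=0, n=3)
        with pytest.raises(ValueError):
            split(data, SplitSpec(train_fraction=0.01, seed=0))


class TestJointAccuracy:
    def test_identical_vectors_are_100(self):
        pairs = np.array([[0, 1], [1, 1], [1, 0]])
        assert joint_accuracy(pairs, pairs) == 100.00

    def test_single_margin_error_fails_whole_row(self):
        true = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [0, 0]])
        assert joint_accuracy(pred, true) == 50.00

    def test_three_of_five_rows_correct(self):
        true = np.array([[1, 1]] * 5)
        pred = np.array([[1, 1], [1, 1], [1, 1], [0, 1], [1, 0]])
        assert joint_accuracy(pred, true) == 60.00

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_accuracy(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(14)
        true = rng.integers(0, 2, size=(30, 2))
        pred = rng.integers(0, 2, size=(30, 2))
        perm = rng.permutation(30)
        assert joint_accuracy(pred, true) == joint_accuracy(pred[perm], true[perm])

    def test_bounded_by_marginal_accuracies(self):
        rng = np.random.default_rng(15)
        true = rng.integers(0, 2, size=(50, 2))
        pred = rng.integers(0, 2, size=(50, 2))
        ja = joint_accuracy(pred, true)
        m1, m2 = marginal_accuracy(pred, true)
        assert ja <= min(m1, m2)


class TestAssociationChi2:
    def test_reconstructed_cohort_table(self, reconstructed_outcomes):
        """The printed cohort counts give p = 0.006 (no continuity correction)."""
        y1, y2 = reconstructed_outcomes
        chi2, p, table = association_chi2(y1, y2)
        np.testing.assert_array_equal(table, [[14, 207], [8, 34]])
        assert round(p, 3) == 0.006

    def test_exact_independence(self):
        y1 = np.r_[np.ones(20), np.zeros(20)]
        y2 = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        chi2, p, _ = association_chi2(y1, y2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, reconstructed_outcomes):
        y1, y2 = reconstructed_outcomes
        chi2, _, table = association_chi2(y1, y2)
        n = table.sum()
        expected = 0.0
        for i in range(2):
            for j in range(2):
                E = table[i].sum() * table[:, j].sum() / n
                expected += (table[i, j] - E) ** 2 / E
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_outcome_swap_and_transpose(self, reconstructed_outcomes):
        y1, y2 = reconstructed_outcomes
        a = association_chi2(y1, y2)
        b = association_chi2(y2, y1)
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])
        np.testing.assert_array_equal(a[2], b[2].T)

    def test_zero_margin_flagged(self):
        with pytest.warns(UserWarning, match="margin"):
            chi2, p, _ = association_chi2(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert np.isnan(p)


class TestCompareModels:
    def test_separable_task_reaches_train_ceiling(self, separable_toy):
        models = default_models(seed=0, hidden_units=4,
                                ga_generations=10, ga_pop_size=10)
        report = compare_models(separable_toy, SplitSpec(seed=1), models)
        assert not report.errors
        for name, m in report.metrics.items():
            assert m["joint_accuracy_train"] == 100.00, name

    def test_joint_bounded_by_marginals_everywhere(self):
        data = mi_cohort_fixture(seed=6)
        models = default_models(seed=2, ga_generations=5, ga_pop_size=8)
        report = compare_models(data, SplitSpec(seed=2), models)
        for m in report.metrics.values():
            for part in ("train", "test"):
                assert m[f"joint_accuracy_{part}"] <= min(
                    m[f"marginal_accuracy_y1_{part}"],
                    m[f"marginal_accuracy_y2_{part}"],
                )

    def test_confusion_counts_sum_to_split_sizes(self):
        data = mi_cohort_fixture(seed=7)
        models = {"BLR": default_models(seed=0)["BLR"]}
        report = compare_models(data, SplitSpec(seed=3), models)
        m = report.metrics["BLR"]
        assert np.sum(m["confusion_train"]) == report.split_sizes[0]
        assert np.sum(m["confusion_test"]) == report.split_sizes[1]

    def test_end_to_end_reproducible(self):
        data = mi_cohort_fixture(seed=8)
        reports = []
        for _ in range(2):
            models = default_models(seed=4, ga_generations=5, ga_pop_size=8)
            reports.append(compare_models(data, SplitSpec(seed=4), models))
        assert reports[0].to_json() == reports[1].to_json()

    def test_model_failure_recorded_not_fatal(self, separable_toy):
        class Broken:
            def fit(self, X, Y):
                raise RuntimeError("nope")

        models = {"bad": Broken(), "BLR": default_models(seed=0)["BLR"]}
        with pytest.warns(UserWarning, match="model bad failed"):
            report = compare_models(separable_toy, SplitSpec(seed=1), models)
        assert "bad" in report.errors and "BLR" in report.metrics
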