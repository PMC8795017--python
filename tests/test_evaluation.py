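"""Evaluation protocols and diagnostic metrics, incl. the published
worked examples that are fully determined by the printed rates."""

import numpy as np
import pandas as pd
import pytest

from otoradiomics.evaluation import (
    ConfusionMatrix,
    bootstrap_ci,
    compute_metrics,
    confusion_from_predictions,
    kfold_plan,
    make_split,
    reconstruct_matrix_from_rates,
    roc_auc,
)


def _cohort(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    rows = []
    for center, (n_pat, n_ctl) in counts.items():
        for i in range(n_pat):
            rows.append({"id": f"{center}p{i}", "label": "patient", "center": center})
        for i in range(n_ctl):
            rows.append({"id": f"{center}c{i}", "label": "control", "center": center})
    return pd.DataFrame(rows)


TABLE1 = {"A": (48, 23), "B": (33, 24), "C": (33, 75), "D": (6, 18)}


class TestSplit:
    def test_study_shaped_cohort_gives_192_68(self):
        plan = make_split(_cohort(TABLE1), "D", 0.26, seed=0)
        assert len(plan.train_ids) == 192
        assert len(plan.test_ids) == 68

    def test_external_center_entirely_in_test(self):
        cohort = _cohort(TABLE1)
        plan = make_split(cohort, "D", 0.26, seed=1)
        d_ids = set(cohort.loc[cohort["center"] == "D", "id"])
        assert d_ids <= set(plan.test_ids)
        assert not d_ids & set(plan.train_ids)

    def test_fraction_covering_only_external_center(self):
        cohort = _cohort({"A": (30, 30), "D": (3, 3)})
        plan = make_split(cohort, "D", 6 / 66, seed=0)
        assert set(plan.test_ids) == set(cohort.loc[cohort["center"] == "D", "id"])

    def test_two_seeds_differ_only_in_random_complement(self):
        cohort = _cohort(TABLE1)
        p1 = make_split(cohort, "D", 0.26, seed=1)
        p2 = make_split(cohort, "D", 0.26, seed=2)
        d_ids = set(cohort.loc[cohort["center"] == "D", "id"])
        assert d_ids <= set(p1.test_ids) and d_ids <= set(p2.test_ids)
        assert set(p1.test_ids) != set(p2.test_ids)

    def test_missing_center_raises(self):
        with pytest.raises(ValueError, match="absent"):
            make_split(_cohort({"A": (5, 5)}), "Z", 0.5, 0)


class TestKFold:
    def test_260_ears_10_folds_of_26(self):
        folds = kfold_plan(_cohort(TABLE1), k=10, seed=0)
        sizes = [len(te) for _, te in folds]
        assert sizes == [26] * 10

    def test_partition_is_disjoint_and_complete(self):
        cohort = _cohort({"A": (13, 14)})
        folds = kfold_plan(cohort, k=5, seed=3)
        seen = [i for _, te in folds for i in te]
        assert sorted(seen) == sorted(cohort["id"])
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_leave_one_out(self):
        cohort = _cohort({"A": (3, 3)})
        folds = kfold_plan(cohort, k=6, seed=0)
        assert all(len(te) == 1 for _, te in folds)

    def test_k_exceeding_n_raises(self):
        with pytest.raises(ValueError):
            kfold_plan(_cohort({"A": (2, 2)}), k=10, seed=0)


class TestMetrics:
    def test_training_column_worked_example(self):
        """The unique integer matrix for sensitivity 80.2% / specificity
        65.6% at 96 vs 96 reproduces the published training metrics."""
        cm = reconstruct_matrix_from_rates(96, 96, 80.2, 65.6)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (77, 19, 63, 33)
        rep = compute_metrics(cm)
        assert round(rep.accuracy, 1) == 72.9
        assert round(rep.ppv, 1) == 70.0
        assert round(rep.npv, 1) == 76.8
        assert round(rep.f1, 2) == 0.75
        assert round(rep.mcc, 2) == 0.46

    def test_test_column_worked_example(self):
        cm = reconstruct_matrix_from_rates(24, 44, 83.4, 81.8)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (20, 4, 36, 8)
        rep = compute_metrics(cm)
        # 56/68 = 82.35%; the published table truncates to 82.3
        assert rep.accuracy == pytest.approx(82.3, abs=0.06)
        assert round(rep.npv, 1) == 90.0
        assert round(rep.f1, 2) == 0.77
        assert round(rep.mcc, 2) == 0.63

    def test_perfect_matrix(self):
        rep = compute_metrics(ConfusionMatrix(10, 0, 10, 0))
        assert rep.accuracy == 100.0
        assert rep.mcc == pytest.approx(1.0)
        assert reconstruct_matrix_from_rates(10, 10, 100, 100) == ConfusionMatrix(10, 0, 10, 0)

    def test_metrics_match_sklearn_on_random_matrices(self):
        """Oracle cross-check against sklearn on 1000 random matrices."""
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(1, 30, size=4)
            y = np.array([1] * (tp + fn) + [0] * (tn + fp))
            p = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
            rep = compute_metrics(confusion_from_predictions(y, p))
            assert rep.accuracy == pytest.approx(100 * accuracy_score(y, p))
            assert rep.sensitivity == pytest.approx(100 * recall_score(y, p))
            assert rep.specificity == pytest.approx(100 * recall_score(1 - y, 1 - p))
            assert rep.ppv == pytest.approx(100 * precision_score(y, p))
            assert rep.f1 == pytest.approx(f1_score(y, p))
            assert rep.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_zero_denominator_yields_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="PPV"):
            rep = compute_metrics(ConfusionMatrix(0, 5, 5, 0))
        assert np.isnan(rep.ppv)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 1, 0)


class TestAUC:
    def test_perfect_ranking(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_four_point_hand_example(self):
        """Pairs: of 2x2 = 4 label pairs, 3 rank the patient higher."""
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(50):
            y = rng.integers(0, 2, size=40)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 5, size=40).astype(float)  # heavy ties
            assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        s = rng.normal(size=60)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s) + 5))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 500)
        s = rng.normal(size=1000)
        assert abs(roc_auc(y, s) - 0.5) < 0.06

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])


class TestBootstrap:
    @staticmethod
    def _acc(y, p):
        return 100.0 * float((y == (p >= 0.5)).mean())

    def test_all_correct_collapses_to_100(self):
        y = np.repeat([0, 1], 10)
        lo, hi = bootstrap_ci(y, y.astype(float), self._acc, reps=200, seed=0)
        assert (lo, hi) == (100.0, 100.0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 50)
        p = np.clip(y + rng.normal(0, 0.6, size=100), 0, 1)
        lo, hi = bootstrap_ci(y, p, self._acc, reps=500, seed=1)
        point = self._acc(y, p)
        assert lo <= point <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (50, 200, 800):
            y = np.repeat([0, 1], n // 2)
            p = np.clip(y + rng.normal(0, 0.8, size=n), 0, 1)
            lo, hi = bootstrap_ci(y, p, self._acc, reps=400, seed=2)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): 16x more data -> ~4x narrower, allow slack
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([0, 1]), np.array([0.1, 0.9]), self._acc)
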