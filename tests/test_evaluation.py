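"""Metric formulas, cross-validation bookkeeping, sampling yields."""

import numpy as np
import pandas as pd
import pytest

from pbfaudit.evaluation import (classification_metrics, cross_quarter_protocol,
                                 kfold_cv, kfold_indices, pr_points,
                                 roc_points, sampling_yield, trapezoid_auc)
from pbfaudit.models import ModelSpec, build_features
from pbfaudit.strategies import srs
from pbfaudit.labeling import label_panel
from pbfaudit.simulate import SimConfig, generate_panel


def _from_confusion(tp, fp, fn, tn):
    y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    return np.array(y_true), np.array(y_pred)


class TestClassificationMetrics:
    def test_hand_computed_confusion_matrix(self):
        y_true, y_pred = _from_confusion(tp=3, fp=1, fn=1, tn=5)
        rep = classification_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.precision[1] == pytest.approx(0.75)
        assert rep.recall[1] == pytest.approx(0.75)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = classification_metrics(y, y)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_absent_class_reported_missing(self):
        rep = classification_metrics([1, 1, 1], [1, 0, 1])
        assert np.isnan(rep.recall[0])

    def test_macro_f1_matches_hand_oracle_on_random_confusions(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            y_true, y_pred = _from_confusion(tp, fp, fn, tn)
            rep = classification_metrics(y_true, y_pred)
            # independent oracle straight from the counts
            p1, r1 = tp / (tp + fp), tp / (tp + fn)
            p0, r0 = tn / (tn + fn), tn / (tn + fp)
            f1_pos = 2 * p1 * r1 / (p1 + r1) if p1 + r1 else 0.0
            f1_neg = 2 * p0 * r0 / (p0 + r0) if p0 + r0 else 0.0
            assert rep.f1 == pytest.approx((f1_pos + f1_neg) / 2)


class TestROC:
    def test_endpoints(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        pts = roc_points(y, rng.random(50))
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 2000)
        auc = trapezoid_auc(roc_points(y, rng.random(2000)))
        n1, n0 = y.sum(), (y == 0).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) <= 3 * se

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        a = trapezoid_auc(roc_points(y, s))
        b = trapezoid_auc(roc_points(y, np.exp(5 * s)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_auc_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        ours = trapezoid_auc(roc_points(y, s))
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_pr_curve_reaches_full_recall(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 100)
        pts = pr_points(y, rng.random(100))
        assert pts[-1][0] == 1.0
        assert pts[-1][1] == pytest.approx(y.mean())

    def test_single_class_roc_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 1, 1], [0.1, 0.2, 0.3])


class TestKFold:
    def test_each_observation_validated_exactly_once(self):
        folds = kfold_indices(103, 10, seed=3)
        assert len(folds) == 10
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(103))

    def test_leave_one_out_boundary(self):
        folds = kfold_indices(10, 10, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 10)

    def test_cv_deterministic_given_seed(self, default_panel, default_labels):
        X = build_features(default_panel, "basic")
        q = X.index.get_level_values("quarter")
        y = default_labels.set_index(["facility_id", "quarter"])[
            "over_report"].reindex(X.index)[q == 1].to_numpy(int)
        spec = ModelSpec("random_forest", {"n_trees": 50, "mtry": 3}, seed=2)
        a = kfold_cv(spec, X[q == 1], y, k=10, seed=5)
        b = kfold_cv(spec, X[q == 1], y, k=10, seed=5)
        assert a.accuracy == b.accuracy and a.f1 == b.f1 and a.auc == b.auc


IDS = [f"F{i:04d}" for i in range(140)]


class TestSamplingYield:
    def test_hypergeometric_mean_for_srs(self):
        # 28 flagged of 140, draws of 70: mean yield = 28/140 = 20%
        flagged = IDS[:28]
        got = sampling_yield(lambda s: srs(IDS, 0.5, s), flagged,
                             reps=1000, seed=0)
        assert abs(got - 0.20) < 0.01

    def test_all_flagged_gives_unit_yield(self):
        got = sampling_yield(lambda s: srs(IDS, 0.3, s), IDS, reps=20, seed=0)
        assert got == 1.0

    def test_none_flagged_gives_zero_yield(self):
        got = sampling_yield(lambda s: srs(IDS, 0.3, s), [], reps=20, seed=0)
        assert got == 0.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            sampling_yield(lambda s: srs(IDS, 0.5, s), IDS, reps=0, seed=0)

    def test_variance_shrinks_as_one_over_reps(self):
        flagged = IDS[:28]
        variances = {}
        for reps in (100, 400, 1600):
            means = [
                sampling_yield(lambda s: srs(IDS, 0.2, s), flagged,
                               reps=reps, seed=seed)
                for seed in range(30)
            ]
            variances[reps] = np.var(means)
        assert variances[100] > variances[400] > variances[1600]
        ratio = variances[100] / variances[1600]
        assert 4 < ratio < 64  # ideal 16, wide Monte-Carlo slack


class TestCrossQuarterProtocol:
    def test_accuracy_tracks_quarter_one(self, default_panel, default_labels):
        spec = ModelSpec("random_forest", {"n_trees": 200, "mtry": 3}, seed=0)
        X = build_features(default_panel, "basic")
        q = X.index.get_level_values("quarter")
        y1 = default_labels.set_index(["facility_id", "quarter"])[
            "over_report"].reindex(X.index)[q == 1].to_numpy(int)
        cv = kfold_cv(spec, X[q == 1], y1, k=10, seed=0)
        later = cross_quarter_protocol(spec, default_panel, default_labels)
        assert set(later) == {"Q2", "Q3", "Q4"}
        for acc in later.values():
            assert abs(acc - cv.accuracy) <= 0.10

    def test_shuffled_labels_fall_to_majority_rate(self, default_panel,
                                                   default_labels):
        rng = np.random.default_rng(9)
        shuffled = default_labels.copy()
        for quarter in (1, 2, 3, 4):
            mask = shuffled["quarter"] == quarter
            vals = shuffled.loc[mask, "over_report"].to_numpy()
            shuffled.loc[mask, "over_report"] = rng.permutation(vals)
        spec = ModelSpec("random_forest", {"n_trees": 100, "mtry": 3}, seed=0)
        later = cross_quarter_protocol(spec, default_panel, shuffled)
        for quarter in (2, 3, 4):
            mask = shuffled["quarter"] == quarter
            majority = max(shuffled.loc[mask, "over_report"].mean(),
                           1 - shuffled.loc[mask, "over_report"].mean())
            assert abs(later[f"Q{quarter}"] - majority) <= 0.12

    def test_single_class_quarter_one_rejected(self, default_panel,
                                               default_labels):
        degenerate = default_labels.copy()
        degenerate.loc[degenerate["quarter"] == 1, "over_report"] = 0
        spec = ModelSpec("naive_bayes", {"density": "normal"})
        with pytest.raises(ValueError):
            cross_quarter_protocol(spec, default_panel, degenerate)
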