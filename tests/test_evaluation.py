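"""Nested-LOSO orchestration, report aggregation, and leakage audit."""

import dataclasses

import numpy as np
import pytest

import emglift as eg
from emglift.evaluation import FoldPlan, curve_agreement, feature_frequency
from emglift.features import WindowGrid
from emglift.selection import OptimalFeatureSet
from emglift.synthetic import noiseless


class TestFoldPlan:
    def test_nine_subjects_nine_outer_eight_inner(self):
        plan = FoldPlan.build([f"S{i:02d}" for i in range(1, 10)])
        assert plan.n_outer == 9
        assert plan.n_inner == 8
        for test, inner in plan.outer:
            for val, train in inner:
                assert test != val
                assert test not in train and val not in train
                assert len(train) == 7

    def test_each_subject_tested_once(self):
        plan = FoldPlan.build(["a", "b", "c", "d"])
        assert sorted(t for t, _ in plan.outer) == ["a", "b", "c", "d"]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan.build(["a", "b"])


class TestRunPipeline:
    def test_toy_run_records_one_set_per_window_and_fold(self, toy_report, toy_grid):
        """3 subjects × 5 windows ⇒ 15 optimal sets; 3 outer × 2 inner folds."""
        assert toy_grid.n_windows == 5
        assert len(toy_report.optimal_sets) == 15
        assert toy_report.fold_plan.n_outer == 3
        assert toy_report.fold_plan.n_inner == 2
        assert toy_report.test_acc_pct.shape == (5, 3)

    def test_noiseless_separable_data_fully_classified_near_onset(self):
        cfg = noiseless(eg.SimConfig(n_subjects=3, lifts_per_class=2,
                                     lift_duration=5.0, onset_time=2.5, seed=2))
        trials = eg.generate_dataset(cfg)
        grid = WindowGrid(region_ms=(-150.0, 150.0))
        report = eg.run_pipeline(trials, grid)
        onset_windows = np.flatnonzero(np.abs(grid.centers_ms) <= 50)
        assert (report.test_acc_pct[onset_windows] == 100.0).all()

    def test_missing_class_raises_with_subject_name(self, toy_trials, toy_grid):
        trimmed = [tr for tr in toy_trials
                   if not (tr.subject_id == "S02" and tr.label == "10-lbs")]
        with pytest.raises(ValueError, match="S02"):
            eg.run_pipeline(trimmed, toy_grid)

    def test_validation_accuracy_traces_non_decreasing(self, toy_report):
        for s in toy_report.optimal_sets:
            assert len(s.features) >= 1
            trace = list(s.accuracy_trace)
            assert trace == sorted(trace)

    def test_leakage_audit_provenance(self, toy_report):
        """No fitted object's provenance may contain its fold's test subject."""
        assert toy_report.audit_passed
        assert toy_report.audit_checks > 0
        for s in toy_report.optimal_sets:
            assert s.test_subject not in s.subjects
            assert len(s.subjects) == len(toy_report.subject_ids) - 1

    def test_accuracy_equals_prevalence_weighted_recall(self, toy_report):
        """Exact aggregate identity, per window and fold, from the confusion
        counts: accuracy = Σ_k n_k·recall_k / Σ_k n_k."""
        counts = toy_report.confusion_counts
        totals = counts.sum(axis=(2, 3))
        correct = np.einsum("wskk->ws", counts)
        np.testing.assert_allclose(
            toy_report.test_acc_pct, 100.0 * correct / totals, atol=1e-9
        )

    def test_deterministic_rerun(self, toy_trials, toy_grid):
        a = eg.run_pipeline(toy_trials, toy_grid)
        b = eg.run_pipeline(toy_trials, toy_grid)
        np.testing.assert_array_equal(a.test_acc_pct, b.test_acc_pct)
        assert [s.features for s in a.optimal_sets] == [s.features for s in b.optimal_sets]


class TestReportAggregation:
    def test_accuracy_curves_bounds_and_shapes(self, toy_report):
        c = toy_report.accuracy_curves()
        assert c["test_mean"].shape == (5,)
        assert ((c["test_mean"] >= 0) & (c["test_mean"] <= 100)).all()
        assert (c["test_sd"] >= 0).all()

    def test_single_outer_fold_sd_is_zero(self):
        rep = _handmade_report()
        rep.test_acc_pct = rep.test_acc_pct[:, :1]
        c = rep.accuracy_curves()
        np.testing.assert_array_equal(c["test_sd"], 0.0)

    def test_confusion_rows_sum_to_100(self, toy_report):
        for w in range(toy_report.grid.n_windows):
            mean, _ = toy_report.confusion_at(w)
            np.testing.assert_allclose(mean.sum(axis=1), 100.0, atol=1e-9)

    def test_confusion_hand_fixture(self):
        """Two folds with hand-built predictions average to the hand-computed
        matrix."""
        rep = _handmade_report()
        mean, sd = rep.confusion_at(0)
        # fold A: class0 2/2 correct; fold B: class0 1/2 correct → mean 75%
        assert mean[0, 0] == pytest.approx(75.0)
        assert mean[0, 1] == pytest.approx(25.0)
        assert sd[0, 0] == pytest.approx(np.std([100.0, 50.0], ddof=1))

    def test_perfect_and_degenerate_classifiers(self):
        rep = _handmade_report()
        W, S, K = 1, 1, 3
        rep.confusion_counts = np.zeros((W, S, K, K), dtype=int)
        rep.confusion_counts[0, 0] = np.diag([2, 2, 2])
        mean, _ = rep.confusion_at(0)
        np.testing.assert_allclose(mean, 100.0 * np.eye(3))
        rep.confusion_counts[0, 0] = 0
        rep.confusion_counts[0, 0, :, 2] = 2  # always predicts the heaviest
        mean, _ = rep.confusion_at(0)
        np.testing.assert_allclose(mean[:, 2], 100.0)
        np.testing.assert_allclose(mean[:, :2], 0.0)

    def test_optimal_windows_pre_and_post(self, default_report):
        pre, post = default_report.optimal_windows()
        ends = default_report.grid.starts_ms + default_report.grid.window_ms
        assert ends[pre] <= 0
        assert default_report.grid.starts_ms[post] >= 0

    def test_per_subject_recall_table_shape(self, toy_report):
        df = toy_report.per_subject_recall()
        assert len(df) == 2 * 3 * 3  # phases × subjects × classes
        assert set(df["phase"]) == {"pre", "post"}


class TestCurveAgreement:
    def test_identical_curves(self):
        x = np.array([50.0, 70.0, 90.0])
        assert curve_agreement(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        assert curve_agreement(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])) == pytest.approx(1.0)

    def test_constant_curve_reported_missing(self):
        r = curve_agreement(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert np.isnan(r)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            curve_agreement(np.ones(3), np.ones(4))


class TestFeatureFrequency:
    def test_single_repeated_set(self):
        sets = [OptimalFeatureSet(("mean-left",), (0.9,))] * 5
        freq = feature_frequency(sets)
        assert freq["selection_pct"]["mean-left"] == 100.0
        assert freq["selection_pct"]["rms-right"] == 0.0
        assert freq["set_size_pct"] == {1: 100.0}

    def test_hand_computed_ledger(self):
        sets = [
            OptimalFeatureSet(("mean-left", "sd-left"), (0.8, 0.9)),
            OptimalFeatureSet(("mean-left",), (0.7,)),
            OptimalFeatureSet(("diff-right", "mean-left", "sd-left"), (0.5, 0.6, 0.7)),
            OptimalFeatureSet(("diff-left",), (0.6,)),
        ]
        freq = feature_frequency(sets)
        assert freq["selection_pct"]["mean-left"] == pytest.approx(75.0)
        assert freq["selection_pct"]["sd-left"] == pytest.approx(50.0)
        assert freq["selection_pct"]["diff-left"] == pytest.approx(25.0)
        assert freq["set_size_pct"] == {1: 50.0, 2: 25.0, 3: 25.0}

    def test_set_size_shares_sum_to_100(self, toy_report):
        freq = feature_frequency(toy_report.optimal_sets)
        assert sum(freq["set_size_pct"].values()) == pytest.approx(100.0)


def _handmade_report() -> eg.EvaluationReport:
    """Minimal report with hand-set confusion counts for arithmetic checks."""
    grid = WindowGrid(region_ms=(-100.0, 100.0))  # 3 windows
    W, S, K = grid.n_windows, 2, 3
    counts = np.zeros((W, S, K, K), dtype=int)
    # window 0, fold A: diag(2,2,2); fold B: class0 split 1/1
    counts[:, 0] = np.diag([2, 2, 2])
    counts[:, 1] = np.diag([1, 2, 2])
    counts[:, 1, 0, 1] = 1
    acc = 100.0 * np.einsum("wskk->ws", counts) / counts.sum(axis=(2, 3))
    return eg.EvaluationReport(
        grid=grid,
        classes=eg.DEFAULT_CLASSES,
        subject_ids=("S01", "S02"),
        test_acc_pct=acc,
        val_acc_pct=acc.copy(),
        confusion_counts=counts,
        optimal_sets=[OptimalFeatureSet(("mean-left",), (0.9,))],
        retained=[[("mean-left",)] * S for _ in range(W)],
    )
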