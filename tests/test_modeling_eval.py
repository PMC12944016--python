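import numpy as np
import pandas as pd
import pytest

from pedalbp.modeling_eval import (
    BPCategory,
    ModelSpec,
    aggregate_subject,
    bland_altman,
    bp_category,
    diagnosis_eval,
    fit_predict,
    grouped_subject_folds,
    metrics,
    monitoring_eval,
    reliability_check,
    rq_kernel,
)


class TestBPCategory:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (118, 76, BPCategory.NORMAL),
            (125, 75, BPCategory.ELEVATED),
            (132, 78, BPCategory.STAGE1),
            (125, 85, BPCategory.STAGE1),
            (145, 95, BPCategory.STAGE2),
            (120, 95, BPCategory.STAGE2),
            (119.9, 79.9, BPCategory.NORMAL),
        ],
    )
    def test_clinical_cut_points(self, sbp, dbp, expected):
        assert bp_category(sbp, dbp) is expected


class TestRQKernel:
    def test_zero_distance_gives_signal_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rq_kernel(x, x, sigma2=2.5) == pytest.approx(2.5)

    def test_unit_distance_reference_value(self):
        assert rq_kernel(np.array([0.0]), np.array([1.0])) == pytest.approx(
            2.0 / 3.0, abs=1e-9
        )

    def test_large_alpha_converges_to_rbf(self):
        val = rq_kernel(np.array([0.0]), np.array([1.0]), alpha=1e8)
        assert val == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rq_kernel(np.zeros(2), np.ones(2), sigma2=-1.0)


class TestMetrics:
    def test_reference_example(self):
        mae, rmse, r2 = metrics([120, 130, 140], [122, 126, 139])
        assert mae == pytest.approx(2.333333, abs=1e-6)
        assert rmse == pytest.approx(2.645751, abs=1e-6)
        assert r2 == pytest.approx(0.895, abs=1e-9)

    def test_perfect_prediction(self):
        assert metrics([120, 130], [120, 130]) == pytest.approx((0.0, 0.0, 1.0))

    def test_mean_predictor_r2_zero(self):
        y = [120.0, 130.0, 140.0]
        _, _, r2 = metrics(y, [130.0] * 3)
        assert r2 == pytest.approx(0.0)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(11)
        y, yh = rng.normal(120, 10, 100), rng.normal(120, 10, 100)
        mae, rmse, _ = metrics(y, yh)
        assert mae <= rmse

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            metrics([120, 120], [118, 122])


class TestBlandAltman:
    def test_perfect_agreement(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == pytest.approx((0.0, 0.0, 0.0))

    def test_reference_differences(self):
        y = np.zeros(4)
        y_hat = np.array([1.0, -1.0, 3.0, -3.0])
        bias, lo, hi = bland_altman(y, y_hat)
        assert bias == pytest.approx(0.0)
        expected = 1.96 * np.sqrt(20.0 / 3.0)  # sample SD of the differences
        assert hi == pytest.approx(expected, abs=1e-9)
        assert lo == pytest.approx(-expected, abs=1e-9)

    def test_constant_offset_shifts_bias_only(self):
        rng = np.random.default_rng(12)
        y = rng.normal(120, 10, 50)
        y_hat = y + rng.normal(0, 2, 50)
        b0, l0, h0 = bland_altman(y, y_hat)
        b1, l1, h1 = bland_altman(y, y_hat + 7.0)
        assert b1 - b0 == pytest.approx(7.0)
        assert h1 - l1 == pytest.approx(h0 - l0)


class TestAggregation:
    def test_median_examples(self):
        assert aggregate_subject([118, 120, 150]) == 120
        assert aggregate_subject([130]) == 130
        assert aggregate_subject([120, 130]) == 125  # midpoint convention

    def test_minority_corruption_bounded(self):
        clean = [118.0, 119.0, 120.0, 121.0, 122.0]
        corrupted = clean[:2] + [v + 100.0 for v in clean[2:4]] + clean[4:]
        assert min(clean) <= aggregate_subject(corrupted) <= max(clean) + 100
        # with <50% corrupted the median stays within the clean range
        corrupted = clean[:3] + [v + 100.0 for v in clean[3:]]
        assert aggregate_subject(corrupted) >= min(clean)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject([])


class TestFitPredict:
    def test_constant_target_predicted_exactly(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((50, 4))
        for family in ("random_forest", "extra_trees", "gradient_boosting"):
            preds = fit_predict(ModelSpec(family=family, M=30, seed=0), X, np.full(50, 117.0),
                                rng.standard_normal((10, 4)))
            np.testing.assert_allclose(preds, 117.0, atol=1e-8)

    def test_noiseless_linear_relation_recovered(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(-1, 1, 400)
        y = 120.0 + 20.0 * x
        X = x.reshape(-1, 1)
        xt = rng.uniform(-0.9, 0.9, 100)
        preds = fit_predict(ModelSpec(family="random_forest", M=500, seed=0), X, y,
                            xt.reshape(-1, 1))
        mae = np.mean(np.abs(preds - (120.0 + 20.0 * xt)))
        assert mae < 0.05 * np.std(y)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((80, 5))
        y = rng.normal(120, 10, 80)
        Xt = rng.standard_normal((20, 5))
        spec = ModelSpec(family="extra_trees", M=50, seed=3)
        np.testing.assert_array_equal(fit_predict(spec, X, y, Xt), fit_predict(spec, X, y, Xt))

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(16)
        X = np.hstack([rng.standard_normal((60, 2)), np.ones((60, 1))])
        y = rng.normal(120, 5, 60)
        preds = fit_predict(ModelSpec(M=20, seed=0), X, y, X[:5])
        assert np.all(np.isfinite(preds))

    def test_gaussian_process_runs(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(-1, 1, 60)
        y = 120 + 15 * x + rng.normal(0, 0.5, 60)
        spec = ModelSpec(family="gaussian_process", kernel="rational_quadratic",
                         n_restarts=0, seed=0)
        preds = fit_predict(spec, x.reshape(-1, 1), y, np.array([[0.5]]))
        assert preds[0] == pytest.approx(127.5, abs=3.0)


class TestGroupedFolds:
    def test_subject_sets_disjoint_every_fold(self):
        groups = np.repeat([f"S{i:02d}" for i in range(11)], 7)
        for train_idx, test_idx in grouped_subject_folds(groups, K=4, seed=0):
            assert not (set(groups[train_idx]) & set(groups[test_idx]))

    def test_every_subject_tested_exactly_once(self):
        groups = np.repeat([f"S{i:02d}" for i in range(9)], 5)
        tested = []
        for _, test_idx in grouped_subject_folds(groups, K=3, seed=1):
            tested.extend(set(groups[test_idx]))
        assert sorted(tested) == sorted(set(groups))

    def test_leave_one_subject_out_limit(self):
        groups = np.repeat(["A", "B", "C"], 4)
        splits = grouped_subject_folds(groups, K=3, seed=0)
        assert all(len(set(groups[test])) == 1 for _, test in splits)

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_subject_folds(np.array(["A", "A", "B"]), K=3, seed=0)


class TestReliability:
    meta = pd.DataFrame(
        {
            "subject_id": ["S1"] * 4,
            "window_index": [3, 4, 5, 6],
            "start_s": [15.0, 20.0, 25.0, 30.0],
            "sbp": [120.0] * 4,
            "dbp": [80.0] * 4,
        }
    )

    def test_smooth_plausible_predictions_unflagged(self):
        flags = reliability_check("sbp", self.meta, np.array([118.0, 119.0, 120.0, 121.0]))
        assert flags == []

    def test_implausible_excursion_flagged(self):
        flags = reliability_check("sbp", self.meta, np.array([118.0, 300.0, 120.0, 121.0]))
        assert any(f["flag"] == "implausible" and f["window_index"] == 4 for f in flags)

    def test_alternating_predictions_flag_every_jump(self):
        flags = reliability_check("sbp", self.meta, np.array([100.0, 160.0, 100.0, 160.0]))
        jumps = [f for f in flags if f["flag"] == "jump"]
        assert len(jumps) == 3
        assert any(f["flag"] == "intra_subject_sd" for f in flags)


class TestProtocols:
    def test_diagnosis_folds_subject_disjoint(self, small_lag_matrix):
        report = diagnosis_eval(small_lag_matrix, ModelSpec(M=20, seed=0), K=4)
        seen = set()
        for subjects in report.fold_assignments.values():
            assert not (seen & set(subjects))
            seen |= set(subjects)
        assert seen == set(small_lag_matrix.groups)

    def test_diagnosis_reports_both_levels(self, small_lag_matrix):
        report = diagnosis_eval(small_lag_matrix, ModelSpec(M=20, seed=0), K=4)
        for level in (report.window_level, report.subject_level):
            assert level["mae"] <= level["rmse"]
            assert level["r2"] <= 1.0
        assert len(report.per_subject) == len(set(small_lag_matrix.groups))

    def test_monitoring_stratification_balanced(self, small_lag_matrix):
        from pedalbp.modeling_eval import _merged_strata

        K = 5
        report = monitoring_eval(small_lag_matrix, ModelSpec(M=20, seed=0), K=K)
        strata = _merged_strata(
            small_lag_matrix.meta["sbp"].to_numpy(),
            small_lag_matrix.meta["dbp"].to_numpy(),
            K,
        )
        n = len(small_lag_matrix)
        global_props = pd.Series(strata, dtype=object).value_counts() / n
        for test_idx in report.fold_assignments.values():
            fold_counts = pd.Series(strata[np.asarray(test_idx)], dtype=object).value_counts()
            for cat, prop in global_props.items():
                expected = prop * len(test_idx)
                assert abs(fold_counts.get(cat, 0) - expected) <= 1.0 + 1e-9

    def test_monitoring_aggregates_every_window_once(self, small_lag_matrix):
        report = monitoring_eval(small_lag_matrix, ModelSpec(M=20, seed=0), K=5)
        covered = sorted(i for idx in report.fold_assignments.values() for i in idx)
        assert covered == list(range(len(small_lag_matrix)))
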