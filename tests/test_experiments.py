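"""Tests for the six-experiment orchestration and the shared split plan."""

import numpy as np
import pytest

from cpdrift import (
    exp1_internal_cv,
    exp2_predict_external,
    exp3_scp,
    exp4_train_update,
    exp5_cal_update,
    exp6_cal_update_half,
    load_models,
    make_split_plan,
    save_models,
)
from cpdrift.evaluation import conformal_error_se
from cpdrift.experiments import SplitPlan


@pytest.fixture(scope="module")
def plan(small_batches):
    return make_split_plan(small_batches.train.y, k_folds=5, n_icps=4, seed=17)


@pytest.fixture(scope="module")
def cv_run(small_batches, plan, centroid_spec):
    b = small_batches.train
    return exp1_internal_cv(b.X, b.y, plan, centroid_spec)


@pytest.fixture(scope="module")
def drifted_cv_run(drifted_batches, centroid_spec):
    b = drifted_batches.train
    plan = make_split_plan(b.y, k_folds=5, n_icps=4, seed=23)
    result, models = exp1_internal_cv(b.X, b.y, plan, centroid_spec)
    return plan, result, models


class TestSplitPlan:
    def test_folds_partition_dataset(self, plan, small_batches):
        n = len(small_batches.train.y)
        all_idx = np.concatenate([plan.fold_test_indices(f) for f in range(5)])
        np.testing.assert_array_equal(np.sort(all_idx), np.arange(n))

    def test_stratified_folds(self, plan, small_batches):
        y = small_batches.train.y
        fracs = [y[plan.fold_test_indices(f)].mean() for f in range(5)]
        assert max(fracs) - min(fracs) < 0.05

    def test_icp_splits_partition_fold_training(self, plan):
        for f in range(plan.k_folds):
            train = set(plan.fold_train_indices(f).tolist())
            for prop, cal in plan.icp_splits[f]:
                assert set(prop.tolist()) | set(cal.tolist()) == train
                assert not set(prop.tolist()) & set(cal.tolist())
                assert abs(len(cal) / (len(cal) + len(prop)) - 0.3) < 0.01

    def test_round_trip(self, plan, tmp_path):
        plan.save(tmp_path / "plan.json")
        assert SplitPlan.load(tmp_path / "plan.json") == plan

    def test_small_class_raises(self):
        y = np.array([0] * 50 + [1] * 3)
        with pytest.raises(ValueError, match="stratify"):
            make_split_plan(y, k_folds=5)

    def test_exact_stratification_counts(self):
        y = np.array([0] * 90 + [1] * 10)
        plan = make_split_plan(y, k_folds=5, n_icps=2, seed=0)
        for f in range(5):
            assert y[plan.fold_test_indices(f)].sum() == 2

    def test_model_archive_round_trip(self, cv_run, tmp_path):
        _, models = cv_run
        save_models(models, tmp_path / "m.joblib")
        back = load_models(tmp_path / "m.joblib")
        assert len(back) == len(models)
        with pytest.raises(ValueError, match="archive"):
            import joblib

            joblib.dump({"something": 1}, tmp_path / "bad.joblib")
            load_models(tmp_path / "bad.joblib")


class TestExperiment1:
    def test_five_fold_curves(self, cv_run):
        result, models = cv_run
        assert len(result.curves) == 5 and len(models) == 5
        assert result.name == "internal_cv"

    def test_internally_valid_at_headline_level(self, cv_run, small_batches):
        result, _ = cv_run
        n_test = len(small_batches.train.y) // 5
        n_cal_active = int(0.3 * 0.8 * small_batches.train.y.sum())
        tol = 3 * conformal_error_se(0.2, n_test, n_cal_active)
        assert result.mean_error_eps02 <= 0.2 + tol

    def test_efficient_on_separable_data(self, cv_run):
        result, _ = cv_run
        assert result.mean_efficiency_eps02 > 0.8


class TestExperiment2:
    def test_exchangeable_external_stays_valid(self, cv_run, small_batches):
        _, models = cv_run
        result = exp2_predict_external(models, small_batches.score.X, small_batches.score.y)
        n_cal_active = int(0.3 * 0.8 * small_batches.train.y.sum())
        tol = 3 * conformal_error_se(0.2, len(small_batches.score.y), n_cal_active)
        assert result.mean_error_eps02 <= 0.2 + tol

    def test_drift_detected(self, drifted_cv_run, drifted_batches):
        _, _, models = drifted_cv_run
        result = exp2_predict_external(models, drifted_batches.score.X, drifted_batches.score.y)
        tol = 3 * conformal_error_se(0.2, len(drifted_batches.score.y), 50)
        assert result.mean_error_eps02 > 0.2 + tol

    def test_one_curve_per_fold_model(self, cv_run, small_batches):
        _, models = cv_run
        result = exp2_predict_external(models, small_batches.score.X, small_batches.score.y)
        assert len(result.curves) == len(models)


class TestExperiment3:
    def test_scp_valid_on_exchangeable_external(self, small_batches, plan, centroid_spec):
        b = small_batches.train
        result = exp3_scp(
            b.X, b.y, plan, small_batches.score.X, small_batches.score.y,
            k=2, spec=centroid_spec,
        )
        assert len(result.curves) == 5
        n_cal_active = int(0.3 * 0.8 * b.y.sum())
        grid = result.curves[0].grid[1:-1]
        for curve in result.curves:
            tol = 3 * conformal_error_se(grid, len(small_batches.score.y), n_cal_active)
            assert np.all(curve.error["overall"][1:-1] <= grid + tol)


class TestExperiment4:
    def test_training_size_bookkeeping(self, small_batches, plan, centroid_spec):
        b = small_batches.train
        upd = small_batches.test
        result, models = exp4_train_update(
            b.X, b.y, upd.X, upd.y, plan, centroid_spec, b.X[:50], b.y[:50]
        )
        expected = len(plan.fold_train_indices(0)) + len(upd.y)
        assert sum(models[0].icps[0].sizes) == round(0.3 * expected)
        assert result.config["update_size"] == len(upd.y)

    def test_drifted_update_improves_calibration(
        self, drifted_cv_run, drifted_batches, centroid_spec
    ):
        plan, _, models = drifted_cv_run
        b = drifted_batches.train
        r2 = exp2_predict_external(models, drifted_batches.score.X, drifted_batches.score.y)
        r4, _ = exp4_train_update(
            b.X, b.y, drifted_batches.test.X, drifted_batches.test.y,
            plan, centroid_spec, drifted_batches.score.X, drifted_batches.score.y,
        )
        # update batch shares the drifted distribution: calibration improves
        assert abs(r4.mean_error_eps02 - 0.2) < abs(r2.mean_error_eps02 - 0.2)


class TestExperiment5:
    def test_no_refit_occurs(self, drifted_cv_run, drifted_batches):
        _, _, models = drifted_cv_run
        before = [id(icp.model) for acp in models for icp in acp.icps]
        exp5_cal_update(
            models, drifted_batches.test.X, drifted_batches.test.y,
            drifted_batches.score.X, drifted_batches.score.y,
        )
        after = [id(icp.model) for acp in models for icp in acp.icps]
        assert before == after

    def test_validity_restored_on_drifted_data(self, drifted_cv_run, drifted_batches):
        _, _, models = drifted_cv_run
        result = exp5_cal_update(
            models, drifted_batches.test.X, drifted_batches.test.y,
            drifted_batches.score.X, drifted_batches.score.y,
        )
        n_cal_active = int(drifted_batches.test.y.sum())
        tol = 3 * conformal_error_se(0.2, len(drifted_batches.score.y), n_cal_active)
        assert abs(result.mean_error_eps02 - 0.2) <= tol

    def test_class_missing_raises(self, drifted_cv_run, drifted_batches):
        _, _, models = drifted_cv_run
        only0 = np.flatnonzero(drifted_batches.test.y == 0)
        with pytest.raises(ValueError, match="both classes"):
            exp5_cal_update(
                models,
                drifted_batches.test.X[only0], drifted_batches.test.y[only0],
                drifted_batches.score.X, drifted_batches.score.y,
            )


class TestExperiment6:
    def test_halves_disjoint_and_stratified(self, drifted_batches):
        from sklearn.model_selection import train_test_split

        y = drifted_batches.score.y
        idx = np.arange(len(y))
        cal, test = train_test_split(idx, test_size=0.5, stratify=y, random_state=3000)
        assert not set(cal) & set(test)
        assert len(set(cal) | set(test)) == len(y)
        assert abs(int(y[cal].sum()) - int(y[test].sum())) <= 1

    def test_validity_restored_by_construction(self, drifted_cv_run, drifted_batches):
        _, _, models = drifted_cv_run
        result = exp6_cal_update_half(
            models, drifted_batches.score.X, drifted_batches.score.y, seed=23
        )
        n_half = len(drifted_batches.score.y) // 2
        n_cal_active = int(drifted_batches.score.y.sum() // 2)
        tol = 3 * conformal_error_se(0.2, n_half, n_cal_active)
        assert abs(result.mean_error_eps02 - 0.2) <= tol


class TestRecoveryOrdering:
    def test_recalibration_beats_stale_calibration(self, drifted_cv_run, drifted_batches):
        """On the standard drift scenario the update strategies restore the
        calibration that direct prediction has lost."""
        _, _, models = drifted_cv_run
        r2 = exp2_predict_external(models, drifted_batches.score.X, drifted_batches.score.y)
        r5 = exp5_cal_update(
            models, drifted_batches.test.X, drifted_batches.test.y,
            drifted_batches.score.X, drifted_batches.score.y,
        )
        r6 = exp6_cal_update_half(
            models, drifted_batches.score.X, drifted_batches.score.y, seed=23
        )
        assert r5.mean_rmsd_overall < r2.mean_rmsd_overall
        assert r6.mean_rmsd_overall < r2.mean_rmsd_overall
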