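"""Unit and property tests for the inductive Mondrian conformal core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdrift import (
    ScoreModelSpec,
    fit_icp,
    margin_nc,
    mondrian_pvalue,
    predict_icp,
    prediction_set,
    prediction_set_matrix,
    recalibrate_icp,
)
from cpdrift.synthetic import DriftScenario, generate


def brute_force_pvalue(cal, test_nc):
    """Independent O(n) recount of the conformal p-value definition."""
    return (sum(1 for c in cal if c >= test_nc) + 1) / (len(cal) + 1)


class TestMarginNC:
    @pytest.mark.parametrize(
        "scores,label,expected",
        [
            ((0.9, 0.1), 1, 0.9),
            ((0.9, 0.1), 0, 0.1),
            ((0.5, 0.5), 0, 0.5),
            ((0.5, 0.5), 1, 0.5),
            ((1.0, 0.0), 0, 0.0),
            ((1.0, 0.0), 1, 1.0),
        ],
    )
    def test_formula(self, scores, label, expected):
        assert margin_nc(np.array(scores), label) == pytest.approx(expected)

    def test_rejects_scores_not_summing_to_one(self):
        with pytest.raises(ValueError):
            margin_nc(np.array([0.7, 0.2]), 0)

    def test_vectorised_matches_scalar(self, rng):
        s1 = rng.random(50)
        scores = np.column_stack([1 - s1, s1])
        labels = rng.integers(0, 2, 50)
        vec = margin_nc(scores, labels)
        for i in range(50):
            assert vec[i] == pytest.approx(margin_nc(scores[i], labels[i]))


class TestMondrianPValue:
    def test_hand_example(self):
        assert mondrian_pvalue(np.array([0.1, 0.2, 0.3, 0.4]), 0.25) == pytest.approx(0.6)

    def test_empty_calibration_gives_one(self):
        assert mondrian_pvalue(np.array([]), 0.7) == 1.0

    def test_nine_achievable_pvalues_with_eight_calibration_points(self, rng):
        """Eight same-class calibration examples -> exactly nine p-values."""
        cal = np.sort(rng.random(8))
        probe = np.concatenate([[-1.0, 2.0], cal, cal - 1e-9, cal + 1e-9, rng.random(500)])
        achieved = {round(float(mondrian_pvalue(cal, t)), 12) for t in probe}
        assert achieved == {round((k + 1) / 9, 12) for k in range(9)}

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 30))
            cal = np.sort(np.round(rng.random(n), 2))  # rounding forces ties
            t = round(float(rng.random()), 2)
            assert mondrian_pvalue(cal, t) == pytest.approx(brute_force_pvalue(cal, t))

    @settings(derandomize=True, max_examples=200)
    @given(
        cal=st.lists(st.floats(0, 1, allow_nan=False), max_size=40),
        t=st.floats(0, 1, allow_nan=False),
    )
    def test_brute_force_property(self, cal, t):
        cal_sorted = np.sort(np.asarray(cal))
        assert mondrian_pvalue(cal_sorted, t) == pytest.approx(
            brute_force_pvalue(cal, t)
        )

    def test_smoothed_bounded_by_nonsmoothed(self, rng):
        cal = np.sort(np.round(rng.random(30), 1))
        for t in np.round(rng.random(50), 1):
            ps = mondrian_pvalue(cal, t, smoothed=True, rng=rng)
            p = mondrian_pvalue(cal, t)
            assert 0 < ps <= p


class TestPredictionSet:
    @pytest.mark.parametrize(
        "p0,p1,eps,expected",
        [
            (0.6, 0.15, 0.2, {0}),
            (0.6, 0.15, 1.0, set()),
            (0.6, 0.15, 0.0, {0, 1}),
            (0.1, 0.1, 0.5, set()),
            (0.3, 0.9, 0.25, {0, 1}),
        ],
    )
    def test_strict_inclusion_rule(self, p0, p1, eps, expected):
        assert prediction_set(p0, p1, eps) == expected

    def test_nestedness_across_epsilon(self, rng):
        pvals = rng.random((200, 2))
        grid = np.linspace(0, 1, 11)
        for e1, e2 in zip(grid[:-1], grid[1:]):
            m1 = prediction_set_matrix(pvals, e1)
            m2 = prediction_set_matrix(pvals, e2)
            assert np.all(m2 <= m1)  # larger epsilon -> subset

    def test_epsilon_out_of_range(self):
        with pytest.raises(ValueError):
            prediction_set(0.5, 0.5, 1.5)


class TestICP:
    def _split(self, batch, rng, n_cal=150):
        idx = rng.permutation(len(batch.y))
        return idx[n_cal:], idx[:n_cal]

    def test_calibration_bookkeeping(self, small_batches, centroid_spec, rng):
        prop, cal = self._split(small_batches.train, rng)
        b = small_batches.train
        icp = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec)
        n0, n1 = icp.sizes
        assert n0 + n1 == len(cal)
        assert n1 == int(b.y[cal].sum())
        for c in (0, 1):
            assert np.all(np.diff(icp.cal_nc[c]) >= 0)
            assert np.all((icp.cal_nc[c] >= 0) & (icp.cal_nc[c] <= 1))

    def test_class_missing_from_calibration_raises(self, small_batches, centroid_spec):
        b = small_batches.train
        only0 = np.flatnonzero(b.y == 0)
        with pytest.raises(ValueError, match="both classes"):
            fit_icp(b.X, b.y, b.X[only0], b.y[only0], centroid_spec)

    def test_separable_toy_data_conforms(self, centroid_spec, rng):
        X0 = rng.normal(size=(60, 2)) + [10, 0]
        X1 = rng.normal(size=(60, 2)) - [10, 0]
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 60)
        icp = fit_icp(X[::2], y[::2], X[1::2], y[1::2], centroid_spec)
        assert np.all(icp.cal_nc[0] < 0.5)
        assert np.all(icp.cal_nc[1] < 0.5)

    def test_refit_is_deterministic(self, small_batches, centroid_spec, rng):
        prop, cal = self._split(small_batches.train, rng)
        b = small_batches.train
        a = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec, seed=3)
        c = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec, seed=3)
        for cls in (0, 1):
            np.testing.assert_array_equal(a.cal_nc[cls], c.cal_nc[cls])

    def test_dimension_mismatch_raises(self, small_batches, centroid_spec, rng):
        prop, cal = self._split(small_batches.train, rng)
        b = small_batches.train
        icp = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec)
        with pytest.raises(ValueError, match="dimension"):
            predict_icp(icp, b.X[:, :5])

    def test_calibration_point_as_test_point(self, small_batches, centroid_spec, rng):
        """A calibration example re-presented scores at least its rank value."""
        prop, cal = self._split(small_batches.train, rng)
        b = small_batches.train
        icp = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec)
        pvals = predict_icp(icp, b.X[cal])
        for i, row in enumerate(cal):
            y = b.y[row]
            n_y = icp.sizes[y]
            assert pvals[i, y] >= 1 / (n_y + 1)
        # oracle recount on the true-class p-value
        from cpdrift.conformal import _class_scores

        scores = _class_scores(icp.model, b.X[cal])
        nc = margin_nc(scores, b.y[cal])
        for i in range(len(cal)):
            y = b.y[cal[i]]
            assert pvals[i, y] == pytest.approx(
                brute_force_pvalue(icp.cal_nc[y], nc[i])
            )

    def test_true_class_pvalues_super_uniform(self, centroid_spec):
        """Under exchangeability, P(p_true <= t) <= t up to MC noise."""
        batches = generate(
            DriftScenario(n_train=1000, n_test=2000, n_score=50, d=20, seed=5)
        )
        b, t = batches.train, batches.test
        rng = np.random.default_rng(5)
        idx = rng.permutation(len(b.y))
        cal, prop = idx[:300], idx[300:]
        icp = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec)
        pvals = predict_icp(icp, t.X)
        p_true = pvals[np.arange(len(t.y)), t.y]
        grid = np.linspace(0.05, 0.95, 19)
        from cpdrift.evaluation import conformal_error_se

        mc_tol = 3 * conformal_error_se(grid, len(t.y), min(icp.sizes))
        emp = np.array([(p_true <= g).mean() for g in grid])
        assert np.all(emp <= grid + mc_tol)

    def test_recalibration_keeps_model(self, small_batches, centroid_spec, rng):
        prop, cal = self._split(small_batches.train, rng)
        b = small_batches.train
        icp = fit_icp(b.X[prop], b.y[prop], b.X[cal], b.y[cal], centroid_spec)
        recal = recalibrate_icp(icp, small_batches.test.X, small_batches.test.y)
        assert recal.model is icp.model
        assert recal.sizes[0] + recal.sizes[1] == len(small_batches.test.y)


def test_svm_spec_constructs_and_validates():
    spec = ScoreModelSpec()
    assert spec.algorithm == "svm" and spec.C == 50.0 and spec.gamma == 0.002
    est = spec.make_estimator(seed=0)
    assert hasattr(est, "fit")
    with pytest.raises(ValueError):
        ScoreModelSpec(C=-1)
    with pytest.raises(ValueError):
        ScoreModelSpec(algorithm="nope").make_estimator()
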