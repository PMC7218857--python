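import numpy as np
import pytest

import imugait as ig
from imugait.correction import (
    DriftCorrector,
    RegressionSpec,
    cross_validate,
    minmax_fit_transform,
    train_regressor,
)
from imugait.kinematics import JointAngleSeries


class TestMinMax:
    def test_endpoints(self):
        scaled, _ = minmax_fit_transform(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(scaled.ravel(), [-1.0, 1.0])

    def test_midpoint(self):
        scaled, _ = minmax_fit_transform(np.array([[0.0], [5.0], [10.0]]))
        assert scaled[1, 0] == pytest.approx(0.0)

    def test_round_trip(self, rng):
        X = rng.uniform(-50, 120, (100, 3))
        scaled, state = minmax_fit_transform(X)
        np.testing.assert_allclose(state.inverse(scaled), X, atol=1e-12)
        assert scaled.min() == pytest.approx(-1.0)
        assert scaled.max() == pytest.approx(1.0)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_fit_transform(np.ones((10, 2)))


class TestShallowNN:
    def test_identity_mapping_learned(self, rng):
        x = rng.uniform(-30, 30, 600)
        model = DriftCorrector(kind="nn", hidden=5, seed=1).fit(
            x.reshape(-1, 1), x)
        pred = model.predict(x.reshape(-1, 1))
        nrmse = np.sqrt(np.mean((pred - x) ** 2)) / np.ptp(x)
        assert nrmse <= 0.01

    def test_constant_offset_removed(self, rng):
        x = rng.uniform(-30, 30, 600)
        y = x.copy()
        model = DriftCorrector(kind="nn", hidden=5, seed=1).fit(
            (x + 3.0).reshape(-1, 1), y)
        resid = model.predict((x + 3.0).reshape(-1, 1)) - y
        assert abs(resid.mean()) <= 0.1

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(-1, 1, (300, 2))
        y = X[:, 0] + 0.1 * X[:, 1]
        a = DriftCorrector(kind="nn", seed=3).fit(X, y).predict(X)
        b = DriftCorrector(kind="nn", seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_hidden_menu_enforced(self):
        with pytest.raises(ValueError, match="5..20"):
            DriftCorrector(kind="nn", hidden=3).fit(np.zeros((10, 1)),
                                                    np.zeros(10))

    def test_stop_reason_recorded(self, rng):
        X = rng.uniform(-1, 1, (200, 2))
        model = DriftCorrector(kind="nn", seed=0).fit(X, X[:, 0])
        assert model.stop_reason_ in {"val_fail", "mse_goal", "grad_min",
                                      "mu_max", "max_iter"}


class TestTree:
    def test_min_leaf_100_on_150_obs_at_most_one_split(self, rng):
        X = rng.uniform(-1, 1, (150, 1))
        y = X[:, 0] + rng.normal(0, 0.01, 150)
        model = DriftCorrector(kind="tree", tree_min_leaf=100,
                               tree_min_branch=2).fit(X, y)
        # at most 1 split -> at most 3 nodes
        assert model.model_.tree_.node_count <= 3

    def test_leaf_menu_enforced(self):
        with pytest.raises(ValueError, match="tree_min_leaf"):
            DriftCorrector(kind="tree", tree_min_leaf=7).fit(
                np.zeros((10, 1)), np.zeros(10))


class TestSvm:
    def test_linear_relation_recovered(self, rng):
        x = rng.uniform(-20, 20, 400)
        model = DriftCorrector(kind="svm", svm_kernel="linear", svm_C=10.0,
                               svm_eps=0.01).fit(x.reshape(-1, 1), 2 * x + 1)
        pred = model.predict(x.reshape(-1, 1))
        assert np.sqrt(np.mean((pred - (2 * x + 1)) ** 2)) / np.ptp(x) < 0.02

    def test_kernel_menu_enforced(self):
        with pytest.raises(ValueError, match="svm_kernel"):
            DriftCorrector(kind="svm", svm_kernel="sigmoid").fit(
                np.zeros((10, 1)), np.zeros(10))

    @pytest.mark.parametrize("kernel", ["quadratic", "cubic", "gaussian"])
    def test_all_kernels_fit(self, kernel, rng):
        X = rng.uniform(-1, 1, (100, 2))
        DriftCorrector(kind="svm", svm_kernel=kernel).fit(X, X[:, 0])


class TestCrossValidate:
    def test_perfect_linear_relation_high_r2(self, rng):
        x = rng.uniform(-30, 30, 800)
        rep = cross_validate(DriftCorrector(kind="nn", seed=2),
                             x.reshape(-1, 1), x, seed=2)
        assert rep.mean_r2 >= 0.99
        assert rep.folds == 5 and len(rep.fold_r2) == 5

    def test_pure_noise_r2_near_zero(self, rng):
        X = rng.uniform(-1, 1, (5000, 2))
        y = rng.normal(0, 1, 5000)
        rep = cross_validate(DriftCorrector(kind="tree", tree_min_leaf=100),
                             X, y, seed=0)
        assert abs(rep.mean_r2) <= 0.1

    def test_repeatable_with_seed(self, rng):
        X = rng.uniform(-1, 1, (300, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 300)
        est = DriftCorrector(kind="tree", tree_min_leaf=12, tree_min_branch=24)
        a = cross_validate(est, X, y, seed=5)
        b = cross_validate(est, X, y, seed=5)
        assert a.fold_nrmse == b.fold_nrmse

    def test_group_folds_user_independent(self):
        X, y, groups = ig.make_regression_benchmark(n_subjects=5, n_cycles=6,
                                                    seed=3)
        rep = cross_validate(DriftCorrector(kind="nn", hidden=5, seed=3),
                             X, y, groups=groups, seed=3)
        assert rep.mean_r2 >= 0.8

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(DriftCorrector(), np.zeros((3, 1)), np.zeros(3))


class TestApplyCorrection:
    def _joints(self, n=400, fs=100.0):
        t = np.arange(n) / fs
        return JointAngleSeries(hip=20 * np.sin(2 * np.pi * t),
                                knee=30 + 25 * np.sin(4 * np.pi * t),
                                ankle=10 * np.sin(2 * np.pi * t + 1), fs=fs)

    def test_empty_series_pass_through(self):
        empty = JointAngleSeries(np.array([]), np.array([]), np.array([]))
        out = ig.apply_correction({}, empty)
        assert len(out) == 0

    def test_identity_training_near_identity_application(self, rng):
        j = self._joints()
        X = np.column_stack([j.ankle, j.angular_velocity("ankle")])
        model = DriftCorrector(kind="nn", hidden=5, seed=4).fit(X, j.ankle)
        out = ig.apply_correction({"ankle": model}, j)
        rmse = np.sqrt(np.mean((out.ankle - j.ankle) ** 2))
        assert rmse <= 0.5
        np.testing.assert_array_equal(out.hip, j.hip)  # untouched joint

    def test_drift_and_offset_removed(self):
        j = self._joints(n=3000)
        t = j.t
        drifted = JointAngleSeries(j.hip, j.knee,
                                   j.ankle - 4.5 + 0.05 * t, fs=j.fs)
        X = np.column_stack([drifted.ankle,
                             drifted.angular_velocity("ankle")])
        model = DriftCorrector(kind="nn", hidden=5, seed=4).fit(X, j.ankle)
        out = ig.apply_correction({"ankle": model}, drifted)
        mean_diff = np.mean(out.ankle - j.ankle)
        assert abs(mean_diff) <= 0.5

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            ig.apply_correction({"ankle": DriftCorrector()}, self._joints())


def test_train_regressor_from_spec(rng):
    x = rng.uniform(-10, 10, 300)
    spec = RegressionSpec(kind="svm", svm_kernel="linear", svm_C=5.0,
                          svm_eps=0.05)
    model = train_regressor(spec, x.reshape(-1, 1), x)
    assert model.predict(np.array([[2.0]])).shape == (1,)
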