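import numpy as np
import pytest

from imugait.metrics import (
    SusResponse,
    agreement_report,
    bland_altman,
    drift_ratio,
    drift_slope,
    nrmse,
    one_sample_ttest,
    pearson_rho,
    sus_score,
    trim_transients,
    turn_drift_increment,
    xapen,
)

from oracles import (
    bland_altman_oracle,
    nrmse_oracle,
    pearson_oracle,
    slope_oracle,
    ttest_oracle,
    xapen_oracle,
)


class TestNrmse:
    def test_identical_series(self, rng):
        x = rng.normal(0, 1, 100)
        assert nrmse(x, x) == 0.0

    def test_constant_offset_arithmetic(self):
        ref = np.array([0.0, 10.0])
        assert nrmse(ref + 1.0, ref) == pytest.approx(0.1)

    def test_matches_oracle(self, rng):
        test = rng.normal(0, 5, 200)
        ref = rng.normal(1, 4, 200)
        assert nrmse(test, ref) == pytest.approx(
            nrmse_oracle(test.tolist(), ref.tolist()), rel=1e-12)

    def test_shift_invariance(self, rng):
        test, ref = rng.normal(0, 3, (2, 150))
        assert nrmse(test + 7.5, ref + 7.5) == pytest.approx(nrmse(test, ref))

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.arange(5.0), np.ones(5))


class TestPearson:
    def test_affine_perfect_correlation(self, rng):
        ref = rng.normal(0, 1, 50)
        assert pearson_rho(2 * ref + 5, ref) == pytest.approx(1.0)
        assert pearson_rho(-ref, ref) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        a, b = rng.normal(0, 1, (2, 10000))
        assert abs(pearson_rho(a, b)) <= 0.05

    def test_affine_invariance(self, rng):
        test, ref = rng.normal(0, 2, (2, 80))
        assert pearson_rho(3 * test + 1, ref) == pytest.approx(
            pearson_rho(test, ref))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_rho(np.ones(10), np.arange(10.0))


class TestXapen:
    def test_constant_pair_is_zero(self):
        assert xapen(np.ones(30), np.ones(30), m=2, r=0.2) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            test = rng.normal(0, 1, 60)
            ref = test + rng.normal(0, 0.3, 60)
            assert xapen(test, ref, r=0.8) == pytest.approx(
                xapen_oracle(test.tolist(), ref.tolist(), r=0.8), rel=1e-10)

    def test_shuffled_reference_less_synchronous(self, rng):
        t = np.arange(300) / 100
        ref = np.sin(2 * np.pi * t)
        shuffled = rng.permutation(ref)
        assert xapen(ref, shuffled, r=0.5) > xapen(ref, ref, r=0.5)

    def test_nonincreasing_in_r(self, rng):
        test = rng.normal(0, 1, 80)
        ref = test + rng.normal(0, 0.2, 80)
        values = [xapen(test, ref, r=r) for r in (0.6, 0.9, 1.2)]
        assert values[0] >= values[1] >= values[2]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            xapen(np.ones(3), np.ones(3), m=2)


class TestDrift:
    def test_exact_line(self):
        t = np.arange(100) / 100
        assert drift_slope(0.01 * t, t) == pytest.approx(0.01)

    def test_whole_period_sinusoid_near_zero(self):
        # discrete sampling leaves an O(1/n) residual around the symmetry zero
        t = np.arange(10000) / 100  # 100 s, whole periods at 1 Hz
        assert abs(drift_slope(np.sin(2 * np.pi * t), t)) <= 1e-3

    def test_sinusoid_plus_trend_matches_oracle(self, rng):
        t = np.arange(3000) / 100
        y = np.sin(2 * np.pi * t) + 0.02 * t + rng.normal(0, 0.05, 3000)
        assert drift_slope(y, t) == pytest.approx(
            slope_oracle(y.tolist(), t.tolist()), rel=1e-10)
        assert drift_slope(y, t) == pytest.approx(0.02, abs=0.005)

    def test_ratio_identity_and_arithmetic(self):
        t = np.arange(500) / 100
        assert drift_ratio(0.04 * t + 1, 0.01 * t, t) == pytest.approx(4.0)
        assert drift_ratio(2 * t, 2 * t, t) == pytest.approx(1.0)

    def test_zero_reference_slope_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(ValueError):
            drift_ratio(t, np.ones(100), t)

    def test_degenerate_time_rejected(self):
        with pytest.raises(ValueError):
            drift_slope(np.arange(5.0), np.zeros(5))


class TestTurnIncrement:
    def test_equal_slopes_zero_percent(self):
        t = np.arange(200) / 100
        assert turn_drift_increment(0.05 * t, t, 100) == pytest.approx(
            0.0, abs=1e-6)

    def test_doubled_slope_hundred_percent(self):
        t = np.arange(200) / 100.0
        y = np.where(t < 1.0, 0.05 * t, 0.05 + 0.10 * (t - 1.0))
        assert turn_drift_increment(y, t, 100) == pytest.approx(100.0,
                                                                abs=1.0)

    def test_turn_at_edge_rejected(self):
        t = np.arange(10) / 10.0
        with pytest.raises(ValueError):
            turn_drift_increment(t, t, 0)


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.normal(0, 1, 50)
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self, rng):
        x = rng.normal(0, 1, 50)
        mean, lo, hi = bland_altman(x + 5.0, x)
        assert (mean, lo, hi) == pytest.approx((5.0, 5.0, 5.0))

    def test_gaussian_differences_closed_form(self, rng):
        ref = np.zeros(10000)
        test = rng.normal(-4.5, 3.0, 10000)
        mean, lo, hi = bland_altman(test, ref)
        assert mean == pytest.approx(-4.5, abs=0.12)
        assert hi - lo == pytest.approx(2 * 1.96 * 3.0, rel=0.05)

    def test_matches_oracle(self, rng):
        test, ref = rng.normal(0, 2, (2, 100))
        np.testing.assert_allclose(
            bland_altman(test, ref),
            bland_altman_oracle(test.tolist(), ref.tolist()), rtol=1e-12)


class TestTTest:
    def test_symmetric_values(self):
        t, p, reject = one_sample_ttest([-1.0, 1.0, -2.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not reject

    def test_power_at_large_n(self, rng):
        t, p, reject = one_sample_ttest(rng.normal(0.1, 1.0, 10000))
        assert reject

    def test_matches_textbook_oracle(self, rng):
        values = rng.normal(0.5, 2.0, 40)
        t, p, _ = one_sample_ttest(values, mu0=0.2)
        t_o, p_o = ttest_oracle(values.tolist(), mu0=0.2)
        assert t == pytest.approx(t_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_ttest(np.ones(10))


class TestSus:
    def test_extremes_and_midpoint(self):
        best = (5, 1) * 5
        worst = (1, 5) * 5
        mid = (3,) * 10
        assert sus_score([best])[1] == 100.0
        assert sus_score([worst])[1] == 0.0
        assert sus_score([mid])[1] == 50.0

    def test_monotone_in_items(self, rng):
        base = [3] * 10
        base_score = SusResponse(tuple(base)).score()
        for i in range(10):
            up = list(base)
            up[i] += 1 if i % 2 == 0 else -1  # improve odd / even item
            assert SusResponse(tuple(up)).score() >= base_score

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SusResponse((0,) + (3,) * 9)
        with pytest.raises(ValueError):
            SusResponse((3,) * 9)


class TestHelpers:
    def test_trim_transients(self):
        t = np.arange(1000) / 100.0
        y = np.arange(1000.0)
        ys, ts = trim_transients(y, t)
        assert ts[0] >= 2.0 and ts[-1] <= t[-1] - 2.0

    def test_agreement_report_fields(self, rng):
        t = np.arange(400) / 100
        ref = np.sin(2 * np.pi * t) * 20
        test = ref + rng.normal(0, 0.5, 400) + 1.0
        rep = agreement_report(test, ref, t)
        d = rep.as_dict()
        assert d["nrmse"] > 0 and abs(d["rho"]) <= 1
        assert d["ba_lo"] <= d["ba_mean_diff"] <= d["ba_hi"]
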