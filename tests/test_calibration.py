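import math

import numpy as np
import pytest

from survalid.calibration import (
    BaselineSurvival,
    WeibullCalibration,
    calibration_slope,
    fit_weibull_calibration,
    fixed_time_calibration_table,
    grouped_calibration_table,
    predicted_survival,
    recalibrated_survival,
    transform_time,
)
from survalid.scoring import builtin_config
from survalid.simulate import rotterdam_like, simulate_cohort


@pytest.fixture(scope="module")
def baseline():
    # table with an exact knot at S0 = 0.8 for the hand-value check
    return BaselineSurvival([(0, 1.0), (6, 0.9), (12, 0.8), (18, 0.7), (24, 0.6)])


@pytest.fixture(scope="module")
def pre_baseline():
    return BaselineSurvival.from_config(builtin_config("erasl_pre"))


def simulate_ph(baseline, lp, rng, gamma=1.0):
    """Inverse-transform event times with S(t|LP) = S0(t)^exp(gamma*LP)."""
    e1 = rng.exponential(1.0, len(lp))
    return baseline.inverse_cumhaz(e1 / np.exp(gamma * lp))


class TestTransformTime:
    def test_knot_value(self, baseline):
        # S0(12) = 0.8  ->  T* = -ln 0.8
        assert transform_time(np.array([12.0]), baseline)[0] == pytest.approx(
            0.2231435513142097, abs=1e-12
        )

    def test_time_zero_floored(self, baseline):
        assert transform_time(np.array([0.0]), baseline)[0] == 1e-10

    def test_monotone(self, baseline):
        ts = np.linspace(0, 24, 101)
        h = transform_time(ts, baseline)
        assert (np.diff(h) >= 0).all()

    def test_beyond_support_raises_unless_extended(self, baseline):
        with pytest.raises(ValueError, match="beyond baseline support"):
            baseline.cumhaz(25.0)
        ext = BaselineSurvival(
            list(zip(baseline.knot_times, baseline.knot_survival)), extend=True
        )
        assert ext.cumhaz(30.0) == pytest.approx(ext.cumhaz(24.0))

    def test_inverse_round_trip(self, baseline):
        ts = np.linspace(0.5, 24, 40)
        back = baseline.inverse_cumhaz(baseline.cumhaz(ts))
        np.testing.assert_allclose(back, ts, rtol=1e-9)


class TestRecalibratedSurvival:
    def test_identity_at_0_0_1(self, baseline):
        # (mu, gamma, sigma) = (0, 0, 1) returns S0(t) for any lp
        for t in np.linspace(1, 24, 12):
            for lp in (-2.0, 0.0, 3.0):
                assert recalibrated_survival(t, lp, (0.0, 0.0, 1.0), baseline) == pytest.approx(
                    float(baseline.survival(t)), abs=1e-12
                )

    def test_ph_identity_at_0_m1_1(self, baseline):
        # (0, -1, 1) returns S0(t)^exp(lp), the original PH prediction
        for t in np.linspace(1, 24, 12):
            for lp in (-1.0, 0.5, 2.0):
                expected = float(baseline.survival(t)) ** math.exp(lp)
                assert recalibrated_survival(t, lp, (0.0, -1.0, 1.0), baseline) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_generic_hand_value(self, baseline):
        # (mu, gamma, sigma) = (-1, -0.6, 1.2) at S0(t) = 0.8, lp = 1:
        # exp(-exp((ln(-ln 0.8) + 1 + 0.6) / 1.2)) = 0.3372406838735328
        got = recalibrated_survival(12.0, 1.0, (-1.0, -0.6, 1.2), baseline)
        assert got == pytest.approx(0.3372406838735328, abs=1e-12)

    def test_probability_bounds_and_t_monotonicity(self, baseline):
        rng = np.random.default_rng(0)
        ts = np.linspace(0.5, 24, 48)
        for _ in range(20):
            mu, gamma = rng.normal(0, 1.5, 2)
            sigma = rng.uniform(0.3, 3.0)
            lp = rng.normal()
            s = np.array([recalibrated_survival(t, lp, (mu, gamma, sigma), baseline) for t in ts])
            assert ((s > 0) & (s < 1)).all()
            assert (np.diff(s) <= 1e-12).all()


class TestCalibrationSlope:
    def test_slope_near_one_under_the_scored_model(self, pre_baseline):
        rng = np.random.default_rng(1)
        covered = 0
        for rep in range(10):
            lp = rng.normal(2.0, 0.8, 800)
            T = simulate_ph(pre_baseline, lp, rng)
            C = rng.uniform(0, 120, len(lp))
            t = np.minimum(np.minimum(T, C), 24.0)
            e = ((T <= C) & (T <= 24.0)).astype(int)
            t = np.maximum(t, 1e-3)
            slope, ci, _ = calibration_slope(lp, t, e)
            if ci[0] <= 1.0 <= ci[1]:
                covered += 1
        assert covered >= 8  # ~95% coverage, allow Monte-Carlo slack

    def test_halved_effect_gives_half_slope(self, pre_baseline):
        rng = np.random.default_rng(2)
        lp = rng.normal(2.0, 0.9, 3000)
        T = simulate_ph(pre_baseline, lp, rng, gamma=0.5)
        t = np.minimum(T, 24.0)
        e = (T <= 24.0).astype(int)
        t = np.maximum(t, 1e-3)
        slope, _, res = calibration_slope(lp, t, e)
        assert slope == pytest.approx(0.5, abs=3 * res.bse[0] + 0.02)

    def test_constant_lp_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope(np.ones(10), np.arange(1.0, 11), np.ones(10, dtype=int))


class TestWeibullCalibrationModel:
    def test_recovers_perfect_calibration(self, pre_baseline):
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(6):
            lp = rng.normal(2.0, 0.8, 1500)
            T = simulate_ph(pre_baseline, lp, rng)
            C = rng.uniform(0, 120, len(lp))
            t = np.maximum(np.minimum(np.minimum(T, C), 24.0), 1e-3)
            e = ((T <= C) & (T <= 24.0)).astype(int)
            cal = fit_weibull_calibration(lp, t, e, pre_baseline)
            ests.append([cal.mu, cal.gamma, cal.sigma])
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        for est, truth, s in zip(ests.mean(axis=0), (0.0, -1.0, 1.0), se):
            assert abs(est - truth) < 3 * max(s, 5e-3)

    def test_attenuated_effect_pulls_gamma_toward_zero(self, pre_baseline):
        rng = np.random.default_rng(4)
        lp = rng.normal(2.0, 0.9, 2500)
        T = simulate_ph(pre_baseline, lp, rng, gamma=0.5)
        t = np.maximum(np.minimum(T, 24.0), 1e-3)
        e = (T <= 24.0).astype(int)
        cal = fit_weibull_calibration(lp, t, e, pre_baseline)
        assert -1.0 < cal.gamma < 0.0
        assert cal.p_gamma_minus_one < 0.05  # detectably different from -1

    def test_round_trip_from_recalibrated_model(self, pre_baseline):
        # generate from the AFT law with known parameters, refit, recover
        truth = (-0.4, -0.7, 1.3)
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(6):
            lp = rng.normal(2.0, 0.9, 2000)
            w = np.log(rng.exponential(1.0, len(lp)))
            tstar = np.exp(truth[0] + truth[1] * lp + truth[2] * w)
            T = pre_baseline.inverse_cumhaz(tstar)
            t = np.maximum(np.minimum(T, 24.0), 1e-3)
            e = (T <= 24.0).astype(int)
            cal = fit_weibull_calibration(lp, t, e, pre_baseline)
            ests.append([cal.mu, cal.gamma, cal.sigma])
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        for est, tr, s in zip(ests.mean(axis=0), truth, se):
            assert abs(est - tr) < 3 * max(s, 5e-3)

    def test_summary_has_perfect_reference_column(self, pre_baseline):
        rng = np.random.default_rng(6)
        lp = rng.normal(2.0, 0.8, 400)
        T = simulate_ph(pre_baseline, lp, rng)
        t = np.maximum(np.minimum(T, 24.0), 1e-3)
        e = (T <= 24.0).astype(int)
        cal = WeibullCalibration(lp, t, e, pre_baseline).fit()
        table = cal.summary()
        assert list(table["perfect"]) == [0.0, -1.0, 1.0]
        assert {"mu", "gamma", "sigma"} == set(table.index)


class TestCalibrationTables:
    @staticmethod
    def scored_cohort(n=600, seed=7, gamma=1.0):
        cfg = rotterdam_like(n=n, gamma_sim=gamma)
        cohort = simulate_cohort(cfg, seed=seed)
        from survalid.scoring import assign_risk_groups, compute_lp_cohort

        sc = builtin_config("erasl_pre")
        lp = compute_lp_cohort(cohort, sc)
        groups = [a.group for a in assign_risk_groups(lp, sc, mode="in_sample")]
        return cohort, lp, groups, BaselineSurvival.from_config(sc)

    def test_grouped_table_well_calibrated_within_km_band(self):
        cohort, lp, groups, baseline = self.scored_cohort()
        table = grouped_calibration_table(cohort.times, cohort.events, lp, groups, baseline)
        for g, sub in table.groupby("group"):
            for t0 in (12.0, 24.0):
                row = sub.iloc[(sub["time"] - t0).abs().argmin()]
                assert row["km_lower"] - 0.02 <= row["predicted_mean"] <= row["km_upper"] + 0.02

    def test_single_group_degenerate_input(self):
        cohort, lp, groups, baseline = self.scored_cohort(n=100)
        table = grouped_calibration_table(
            cohort.times, cohort.events, lp, ["low"] * len(lp), baseline
        )
        assert set(table["group"]) == {"low"}

    def test_recalibration_moves_curves_toward_km_when_miscalibrated(self):
        # generate with halved effect: the original predictions misstate the
        # spread, the recalibrated ones must track the KM curves closer
        cohort, lp, groups, baseline = self.scored_cohort(n=1500, seed=8, gamma=0.5)
        t, e = cohort.times, cohort.events
        cal = fit_weibull_calibration(lp, t, e, baseline)
        table = grouped_calibration_table(t, e, lp, groups, baseline, cal=cal)
        dist_orig = np.abs(table["predicted_mean"] - table["km"]).sum()
        dist_recal = np.abs(table["recalibrated_mean"] - table["km"]).sum()
        assert dist_recal < dist_orig

    def test_fixed_time_points_on_diagonal_when_calibrated(self):
        cohort, lp, groups, baseline = self.scored_cohort(n=1000, seed=9)
        table = fixed_time_calibration_table(
            cohort.times, cohort.events, lp, groups, baseline, times=(12.0, 24.0)
        )
        inside = (
            (table["predicted_mean"] >= table["km_lower"] - 0.03)
            & (table["predicted_mean"] <= table["km_upper"] + 0.03)
        )
        assert inside.mean() >= 0.8

    def test_optimistic_model_sits_below_diagonal(self):
        # shift every prediction up: observed < predicted at every point
        cohort, lp, groups, baseline = self.scored_cohort(n=800, seed=10)
        optimistic_lp = lp - 1.2  # lower score -> higher predicted survival
        table = fixed_time_calibration_table(
            cohort.times, cohort.events, optimistic_lp, groups, baseline, times=(12.0, 24.0)
        )
        assert (table["km"] < table["predicted_mean"]).all()

    def test_predicted_survival_on_published_scale(self, pre_baseline):
        # lp = 0 reproduces the baseline itself
        s = predicted_survival(np.array([6.0, 12.0]), np.array([0.0]), pre_baseline)
        np.testing.assert_allclose(s[0], pre_baseline.survival(np.array([6.0, 12.0])), rtol=1e-12)
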