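import numpy as np
import pytest

from survalid.survival import (
    CoxPH,
    WeibullAFT,
    fit_cox,
    fit_weibull_aft,
    kaplan_meier,
    km_median_ci,
    lr_test,
)


def cox_logpl_efron(beta, X, t, e, offset=None):
    """Independent brute-force Efron log partial likelihood (written-out sums)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta + (0 if offset is None else offset)
    ll = 0.0
    for u in np.unique(t[e == 1]):
        D = np.nonzero((t == u) & (e == 1))[0]
        R = np.nonzero(t >= u)[0]
        d = len(D)
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(np.exp(eta[R]).sum() - (l / d) * np.exp(eta[D]).sum())
    return ll


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times 2, 4+, 5, 7+: S = 3/4 after t=2, then 3/4 * 1/2 after t=5
        km = kaplan_meier([2, 4, 5, 7], [1, 0, 1, 0])
        np.testing.assert_allclose(km.event_times, [2, 5])
        np.testing.assert_allclose(km.survival, [0.75, 0.375])

    def test_survival_starts_at_one(self):
        km = kaplan_meier([3, 6, 9], [1, 1, 0])
        assert km.survival_at(0.0) == 1.0
        assert km.survival_at(2.9) == 1.0

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(1, 10, 40)
        km = kaplan_meier(t, np.ones(40, dtype=int))
        grid = np.linspace(0, 11, 23)
        empirical = [(t > g).mean() for g in grid]
        np.testing.assert_allclose(np.asarray(km.survival_at(grid)), empirical, atol=1e-12)

    def test_censoring_at_event_time_stays_in_risk_set(self):
        # censored subject at t=2 must count in the risk set of the t=2 event
        # risk set at t=2 is all 3 subjects (not 2), giving S(2) = 2/3
        km = kaplan_meier([2, 2, 5], [1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = np.round(rng.uniform(1, 20, 100), 0) + 0.5
        e = rng.integers(0, 2, 100)
        km = kaplan_meier(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        grid = np.unique(t)
        np.testing.assert_allclose(
            np.asarray(km.survival_at(grid)), kmf.predict(grid).to_numpy(), atol=1e-10
        )


class TestKMedian:
    def test_never_below_half_is_not_reached(self):
        km = kaplan_meier([5, 10, 15, 20, 25], [1, 0, 0, 0, 0])  # S stays at 0.8
        median, _ = km_median_ci(km)
        assert median is None

    def test_uncensored_odd_sample_median(self):
        t = np.array([3.0, 7.0, 11.0])
        km = kaplan_meier(t, [1, 1, 1])
        median, _ = km_median_ci(km)
        assert median == 7.0

    def test_step_crossing_lookup(self):
        # survival drops to exactly 0.5 at t=17 and below afterwards
        km = kaplan_meier([17, 17, 20, 20], [1, 1, 1, 0])
        median, (lo, hi) = km_median_ci(km)
        assert median == 17.0
        assert lo is None or lo <= median
        assert hi is None or hi >= median


class TestCoxPH:
    def test_single_covariate_matches_grid_search(self):
        # 6 uncensored records, distinct times, one binary covariate
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        res = fit_cox(x, t, e)
        grid = np.linspace(-3, 3, 120001)
        vals = [cox_logpl_efron(b, x[:, None], t, e) for b in grid]
        best = grid[int(np.argmax(vals))]
        assert res.params[0] == pytest.approx(best, abs=1e-4)
        assert res.llf == pytest.approx(cox_logpl_efron(res.params, x[:, None], t, e), abs=1e-10)

    def test_efron_ties_match_brute_force_likelihood(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        t = np.round(t, 1) + 0.05  # force ties
        res = fit_cox(X, t, e)
        assert res.llf == pytest.approx(cox_logpl_efron(res.params, X, t, e), rel=1e-10)
        # gradient-zero at optimum: nearby perturbations never improve
        for j in range(3):
            for h in (-1e-4, 1e-4):
                b = res.params.copy()
                b[j] += h
                assert cox_logpl_efron(b, X, t, e) <= res.llf + 1e-12

    def test_scaled_covariate_identity(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        x = X[:, :1]
        c = 3.7
        res1 = fit_cox(x, t, e)
        res2 = fit_cox(x / c, t, e)
        assert res2.params[0] == pytest.approx(c * res1.params[0], rel=1e-8)

    def test_null_with_zero_offset_is_null_likelihood(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        res_free = fit_cox(X[:, :1], t, e)
        res_null = fit_cox(None, t, e, offset=np.zeros(len(t)))
        assert res_null.llf == pytest.approx(res_free.llnull, abs=1e-10)

    def test_offset_recovers_unit_coefficient(self):
        # simulate from hazard exp(1.0 * x); offsetting x should leave ~0
        # free effect, and fitting x freely should give a coefficient near 1
        rng = np.random.default_rng(11)
        n = 1500
        x = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(x))
        C = rng.exponential(2.0, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        free = fit_cox(x, t, e)
        assert free.params[0] == pytest.approx(1.0, abs=3 * free.bse[0])
        dup = fit_cox(x, t, e, offset=x)  # x both free and as offset
        assert dup.params[0] == pytest.approx(free.params[0] - 1.0, abs=1e-6)

    def test_offset_shifts_loglik_consistently(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        off = X @ np.array([0.5, -0.3, 0.8])
        res = fit_cox(None, t, e, offset=off)
        assert res.llf == pytest.approx(cox_logpl_efron(np.zeros(0), np.empty((len(t), 0)), t, e, off), rel=1e-10)

    def test_matches_lifelines(self, sim_cox_data):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        X, t, e, _ = sim_cox_data
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        res = fit_cox(X, t, e, names=["a", "b", "c"])
        np.testing.assert_allclose(res.params, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.bse, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_constant_column_rejected_by_name(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        X = X.copy()
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="b"):
            fit_cox(X, t, e, names=["a", "b", "c"])

    def test_breslow_baseline_nondecreasing_from_zero(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        res = fit_cox(X, t, e)
        bh = res.baseline_cumhaz
        assert (np.diff(bh["cumhaz"]) >= 0).all()
        assert bh["cumhaz"].iloc[0] > 0
        assert bh["time"].iloc[0] == t[e == 1].min()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            CoxPH(np.ones((3, 1)) * [[1], [2], [3]], [1, 2, 3], [0, 0, 0])


class TestLRTest:
    def test_identical_fits_statistic_zero(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        res = fit_cox(X[:, :1], t, e)
        stat, p = lr_test(res, res, df=1)
        assert stat == 0.0 and p == 1.0

    def test_strong_covariate_agrees_with_wald(self):
        rng = np.random.default_rng(21)
        n = 500
        x = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(0.9 * x))
        C = rng.exponential(3.0, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        full = fit_cox(x, t, e)
        null = fit_cox(None, t, e, offset=np.zeros(n))
        stat, _ = lr_test(null, full, df=1)
        wald = (full.params[0] / full.bse[0]) ** 2
        assert stat == pytest.approx(wald, rel=0.2)

    def test_mis_nesting_detected(self, sim_cox_data):
        X, t, e, _ = sim_cox_data
        big = fit_cox(X, t, e)
        small = fit_cox(X[:, :1], t, e)
        with pytest.raises(ValueError):
            lr_test(big, small, df=2)  # swapped order -> negative statistic


class TestWeibullAFT:
    @staticmethod
    def draw(rng, n, mu, gamma, sigma, censor_scale=None):
        lp = rng.normal(size=n)
        w = np.log(rng.exponential(1.0, n))  # standard minimum extreme value
        T = np.exp(mu + gamma * lp + sigma * w)
        if censor_scale is None:
            return lp, T, np.ones(n, dtype=int)
        C = rng.exponential(censor_scale, n)
        return lp, np.minimum(T, C), (T <= C).astype(int)

    def test_parameter_recovery(self):
        mu, gamma, sigma = -1.0, -0.6, 1.2
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(8):
            lp, t, e = self.draw(rng, 2000, mu, gamma, sigma, censor_scale=2.0)
            r = fit_weibull_aft(lp, t, e)
            ests.append([r.mu, r.gamma, r.sigma])
            assert 0.1 < e.mean() < 1.0
        ests = np.array(ests)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        for est, truth, se in zip(ests.mean(axis=0), (mu, gamma, sigma), mc_se):
            assert abs(est - truth) < 3 * max(se, 1e-3)

    def test_lp_location_shift_identity(self):
        rng = np.random.default_rng(6)
        lp, t, e = self.draw(rng, 400, 0.5, -0.8, 0.9, censor_scale=3.0)
        r1 = fit_weibull_aft(lp, t, e)
        r2 = fit_weibull_aft(lp + 2.0, t, e)
        assert r2.gamma == pytest.approx(r1.gamma, abs=1e-6)
        assert r2.mu == pytest.approx(r1.mu - 2.0 * r1.gamma, abs=1e-5)
        assert r2.sigma == pytest.approx(r1.sigma, abs=1e-6)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            WeibullAFT([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0, 0, 0])

    def test_intercept_only_matches_profile_search(self):
        # uncensored intercept-only fit vs 2-D profile grid on (mu, sigma)
        rng = np.random.default_rng(9)
        t = np.exp(0.4 + 0.8 * np.log(rng.exponential(1.0, 300)))
        e = np.ones(300, dtype=int)
        r = WeibullAFT(None, t, e).fit()
        logt = np.log(t)

        def nll(mu, sigma):
            z = (logt - mu) / sigma
            return -np.sum(-np.log(sigma) + z - np.exp(z))

        mus = np.linspace(r.mu - 0.05, r.mu + 0.05, 201)
        sigs = np.linspace(r.sigma - 0.05, r.sigma + 0.05, 201)
        grid = np.array([[nll(m, s) for s in sigs] for m in mus])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        assert mus[i] == pytest.approx(r.mu, abs=1e-3)
        assert sigs[j] == pytest.approx(r.sigma, abs=1e-3)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(12)
        lp, t, e = self.draw(rng, 600, -0.5, -0.7, 1.1, censor_scale=1.5)
        r = fit_weibull_aft(lp, t, e)
        df = pd.DataFrame({"lp": lp, "T": t, "E": e})
        wf = lifelines.WeibullAFTFitter().fit(df, "T", "E")
        assert r.gamma == pytest.approx(wf.params_[("lambda_", "lp")], abs=1e-4)
        assert r.mu == pytest.approx(wf.params_[("lambda_", "Intercept")], abs=1e-4)
        assert r.sigma == pytest.approx(1 / np.exp(wf.params_[("rho_", "Intercept")]), abs=1e-4)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        lp, t, e = self.draw(rng, 200, 0.0, -1.0, 1.0, censor_scale=2.0)
        r1 = fit_weibull_aft(lp, t, e)
        r2 = fit_weibull_aft(lp, t, e)
        assert r1.params.tolist() == r2.params.tolist()
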