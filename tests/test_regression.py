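"""Censored regression: likelihood assembly, fitting, residuals, KM."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.tools import numdiff

from trunclindley import (TLW, CensoredData, TLWModel, TLWRegression,
                          WeibullRegression, kaplan_meier, tlw_loglik)
from trunclindley.utl import utl_ppf


def _simulate(rng, n=120, theta=0.6, b1=(0.3, 0.4), b2=(0.2, 0.5),
              censor=0.25):
    v1 = rng.binomial(1, 0.5, n).astype(float)
    V = np.column_stack([np.ones(n), v1])
    lam = np.exp(V @ np.asarray(b1))
    k = np.exp(V @ np.asarray(b2))
    y = utl_ppf(rng.uniform(size=n), theta)
    x_star = lam * (-np.log1p(-y)) ** (1.0 / k)
    if censor > 0:
        c = rng.uniform(0, np.quantile(x_star, 1 - censor) * 2, n)
        x = np.minimum(x_star, c)
        delta = (x_star < c).astype(int)
    else:
        x, delta = x_star, np.ones(n, dtype=int)
    return x, delta, V


class TestData:
    def test_validation(self):
        with pytest.raises(ValueError):
            CensoredData.build([1.0, -1.0], [1, 0], np.ones((2, 1)))
        with pytest.raises(ValueError):
            CensoredData.build([1.0, 2.0], [1, 2], np.ones((2, 1)))

    def test_rank_deficiency_reported(self):
        V = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank deficient"):
            CensoredData.build(np.arange(1.0, 6.0), np.ones(5, int), V)

    def test_from_dataframe(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 0, 1, 1],
                           "age": [30.0, 40, 50, 60]})
        data = CensoredData.from_dataframe(df, scale_covariates=["age"])
        assert data.exog_scale.shape == (4, 2)
        assert data.scale_names == ("intercept", "age")
        assert data.n_events == 3


class TestLikelihood:
    def test_reduces_to_univariate_when_uncensored_intercept_only(
            self, temperatures):
        V = np.ones((temperatures.size, 1))
        m = TLWRegression(temperatures, np.ones(temperatures.size, int), V, V)
        th, k, lam = -5.0, 3.0, 13.0
        p = np.array([th, np.log(lam), np.log(k)])
        assert m.loglike(p) == pytest.approx(
            tlw_loglik(temperatures, th, k, lam), rel=1e-12)

    def test_assembled_from_density_and_survival(self, rng):
        x, delta, V = _simulate(rng)
        m = TLWRegression(x, delta, V, V)
        th, b1, b2 = 0.8, np.array([0.4, 0.3]), np.array([0.1, 0.4])
        lam, k = np.exp(V @ b1), np.exp(V @ b2)
        manual = sum(
            float(TLW(th, k[i], lam[i]).logpdf(x[i])) if delta[i]
            else float(TLW(th, k[i], lam[i]).logsf(x[i]))
            for i in range(x.size)
        )
        assert m.loglike(np.concatenate([[th], b1, b2])) == pytest.approx(
            manual, rel=1e-10)

    def test_row_order_invariance(self, rng):
        x, delta, V = _simulate(rng)
        p = np.array([0.6, 0.3, 0.4, 0.2, 0.5])
        m1 = TLWRegression(x, delta, V, V)
        perm = rng.permutation(x.size)
        m2 = TLWRegression(x[perm], delta[perm], V[perm], V[perm])
        assert m1.loglike(p) == pytest.approx(m2.loglike(p), rel=1e-12)

    @pytest.mark.parametrize("theta", [-3.0, -0.4, 0.7, 2.5])
    def test_analytic_score_matches_finite_differences(self, rng, theta):
        x, delta, V = _simulate(rng, n=60)
        m = TLWRegression(x, delta, V, V)
        p = np.array([theta, 0.3, 0.4, 0.2, 0.5])
        fd = numdiff.approx_fprime(p, m.loglike, centered=True)
        assert np.allclose(m.score(p), fd, rtol=1e-6, atol=1e-5)

    def test_weibull_score_matches_finite_differences(self, rng):
        x, delta, V = _simulate(rng, n=60)
        m = WeibullRegression(x, delta, V, V)
        p = np.array([0.3, 0.4, 0.2, 0.5])
        fd = numdiff.approx_fprime(p, m.loglike, centered=True)
        assert np.allclose(m.score(p), fd, rtol=1e-6, atol=1e-5)


class TestFit:
    def test_intercept_only_matches_univariate_fit(self, carbon_fibers):
        V = np.ones((carbon_fibers.size, 1))
        reg = TLWRegression(carbon_fibers, np.ones(carbon_fibers.size, int),
                            V, V).fit(theta_starts=(-40.0, -10.0, -2.0, -0.5,
                                                    0.5, 2.0, 10.0, 40.0))
        uni = TLWModel(carbon_fibers).fit()
        assert reg.loglik == pytest.approx(uni.loglik, abs=5e-4)

    def test_aic_equals_deviance_plus_dimension(self, rng):
        x, delta, V = _simulate(rng)
        res = TLWRegression(x, delta, V, V).fit()
        assert res.aic == pytest.approx(res.global_deviance + 2 * res.p)

    def test_recovers_truth_on_large_sample(self, rng):
        x, delta, V = _simulate(rng, n=4000, censor=0.1)
        res = TLWRegression(x, delta, V, V).fit()
        truth = np.array([0.6, 0.3, 0.4, 0.2, 0.5])
        assert np.all(np.abs(res.params - truth) < 4 * np.maximum(res.se, 0.1))

    def test_summary_and_pvalues(self, rng):
        x, delta, V = _simulate(rng)
        res = TLWRegression(x, delta, V, V).fit()
        assert res.pvalues.shape == (5,)
        assert np.all((res.pvalues >= 0) & (res.pvalues <= 1))
        assert "censored regression" in res.summary()


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(77)
    x, delta, V = _simulate(rng, n=200)
    model = TLWRegression(x, delta, V, V)
    return model.fit()


class TestResiduals:
    def test_martingale_identities(self, fitted):
        rm = fitted.martingale_residuals()
        delta = fitted.model.data.event
        assert np.all(rm <= 1.0 + 1e-12)
        # censored observation with S ~ 1 carries ~0 signal
        logS = rm - delta
        early = (delta == 0) & (logS > -1e-3)
        assert np.all(np.abs(rm[early]) < 1e-3)

    def test_martingale_zero_when_survival_is_exp_minus_one(self):
        # uncensored with S = e^{-1}: r_M = 1 + log S = 0
        rng = np.random.default_rng(3)
        x, delta, V = _simulate(rng, n=50, censor=0.0)
        res = TLWRegression(x, delta, V, V).fit()
        th, b1, b2 = res.params[0], res.params[1:3], res.params[3:5]
        lam = np.exp(V[0] @ b1)
        k = np.exp(V[0] @ b2)
        from scipy.optimize import brentq
        d = TLW(th, k, lam)
        x_star = brentq(lambda t: d.logsf(t) + 1.0, 1e-6, 100)
        # patch first observation to sit exactly at S = e^{-1}
        x2 = x.copy()
        x2[0] = x_star
        res2 = TLWRegression(x2, delta, V, V)
        rm = res2.data.event[0] + float(d.logsf(x_star))
        assert rm == pytest.approx(0.0, abs=1e-10)

    def test_martingale_mean_near_zero_when_well_specified(self):
        rng = np.random.default_rng(11)
        x, delta, V = _simulate(rng, n=2000, censor=0.0)
        res = TLWRegression(x, delta, V, V).fit()
        rm = res.martingale_residuals()
        assert abs(rm.mean()) < 3.0 / np.sqrt(rm.size)

    def test_deviance_identities_and_sign(self, fitted):
        rd = fitted.deviance_residuals()
        rm = fitted.martingale_residuals()
        assert np.all(np.sign(rd) == np.sign(rm))
        # r_M = 0 maps to r_D = 0 for either censoring status
        for delta in (0.0, 1.0):
            inner = delta - 0.0
            core = -2 * (0.0 + delta * np.log(inner)) if delta else 0.0
            assert np.sign(0.0) * np.sqrt(max(core, 0.0)) == 0.0

    def test_deviance_mostly_within_three(self):
        rng = np.random.default_rng(21)
        x, delta, V = _simulate(rng, n=1000, censor=0.1)
        res = TLWRegression(x, delta, V, V).fit()
        rd = res.deviance_residuals()
        assert np.mean(np.abs(rd) < 3.0) > 0.99

    def test_quantile_residuals(self):
        rng = np.random.default_rng(31)
        x, delta, V = _simulate(rng, n=200, censor=0.0)
        res = TLWRegression(x, delta, V, V).fit()
        q = res.quantile_residuals()
        from scipy.stats import shapiro
        assert shapiro(q).pvalue > 0.01
        # monotone in x within a covariate pattern
        pat = V[:, 1] == 0
        order = np.argsort(x[pat])
        assert np.all(np.diff(q[pat][order]) > 0)

    def test_quantile_residuals_require_uncensored(self, fitted):
        if fitted.model.data.n_events < fitted.model.data.n:
            with pytest.raises(ValueError):
                fitted.quantile_residuals()


class TestKaplanMeier:
    def test_no_censoring_gives_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        times, surv = kaplan_meier(t, np.ones(4, int))[None]
        assert np.allclose(times, t)
        assert np.allclose(surv, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])[None]
        assert km[0].size == 0

    def test_matches_lifelines_oracle(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(20):
            n = rng.integers(10, 60)
            t = rng.exponential(2.0, n)
            e = rng.binomial(1, 0.7, n)
            if e.sum() == 0:
                continue
            kmf = lifelines.KaplanMeierFitter().fit(t, e)
            times, surv = kaplan_meier(t, e)[None]
            ref = kmf.survival_function_at_times(times).to_numpy()
            assert np.allclose(surv, ref, atol=1e-10)

    def test_grouped(self):
        t = np.array([1.0, 2.0, 1.5, 2.5])
        e = np.array([1, 1, 1, 1])
        g = np.array(["a", "a", "b", "b"])
        km = kaplan_meier(t, e, g)
        assert set(km) == {"a", "b"}
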