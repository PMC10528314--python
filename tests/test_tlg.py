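"""Generic composed family: composition identities, moments, entropies."""

import numpy as np
import pytest
from scipy import integrate

from trunclindley import TLG, uniform_parent, utl_cdf, utl_pdf, weibull_parent


@pytest.fixture(scope="module")
def tlg_weibull():
    return TLG(0.5, weibull_parent(2.0, 2.0))


class TestComposition:
    def test_uniform_parent_reduces_to_unit_law(self):
        g = TLG(1.7, uniform_parent())
        xs = np.linspace(0.01, 0.99, 25)
        assert np.allclose(g.cdf(xs), utl_cdf(xs, 1.7))
        assert np.allclose(g.pdf(xs), utl_pdf(xs, 1.7))

    def test_cdf_is_unit_law_of_parent_cdf(self, tlg_weibull, rng):
        xs = rng.uniform(0.05, 6, 20)
        parent = tlg_weibull.parent
        assert np.allclose(tlg_weibull.cdf(xs),
                           utl_cdf(parent.cdf(xs), tlg_weibull.theta))

    def test_support_limits(self, tlg_weibull):
        assert tlg_weibull.cdf(1e-12) == pytest.approx(0.0, abs=1e-10)
        assert tlg_weibull.cdf(50.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [-50.0, -5.0, -0.5, 0.5, 5.0, 50.0])
    @pytest.mark.parametrize("parent_kind", ["weibull", "uniform"])
    def test_pdf_normalises(self, theta, parent_kind):
        parent = weibull_parent(1.5, 2.0) if parent_kind == "weibull" \
            else uniform_parent()
        g = TLG(theta, parent)
        hi = parent.support[1] if np.isfinite(parent.support[1]) else np.inf
        val, _ = integrate.quad(lambda x: g.pdf(x), parent.support[0], hi,
                                limit=400)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_logpdf_finite_for_strongly_negative_theta(self):
        g = TLG(-49.5, weibull_parent(1.374, 1.0295))
        lp = g.logpdf(np.array([0.3, 1.0, 2.5, 4.0]))
        assert np.all(np.isfinite(lp))

    def test_pdf_is_cdf_derivative(self, tlg_weibull):
        xs = np.linspace(0.3, 4.0, 9)
        h = 1e-6
        fd = (tlg_weibull.cdf(xs + h) - tlg_weibull.cdf(xs - h)) / (2 * h)
        assert np.allclose(fd, tlg_weibull.pdf(xs), rtol=1e-6)


class TestQuantiles:
    @pytest.mark.parametrize("theta", [-49.5, -2.0, 0.5, 3.0])
    def test_inversion(self, theta):
        g = TLG(theta, weibull_parent(2.0, 1.5))
        u = np.array([0.01, 0.25, 0.5, 0.75, 0.99])
        assert np.allclose(g.cdf(g.ppf(u)), u, atol=1e-9)

    def test_against_bisection(self):
        from scipy.optimize import brentq
        g = TLG(-2.0, weibull_parent(1.3, 2.0))
        for u in (0.1, 0.6, 0.95):
            ref = brentq(lambda t: g.cdf(t) - u, 1e-9, 60, xtol=1e-12)
            assert g.ppf(u) == pytest.approx(ref, abs=1e-8)


class TestMoments:
    def test_zeroth_moment_is_one(self, tlg_weibull):
        assert tlg_weibull.moment(0) == 1.0

    def test_matches_monte_carlo(self, tlg_weibull):
        x = tlg_weibull.rvs(200_000, rng=1)
        for k in (1, 2):
            mk = tlg_weibull.moment(k)
            se = np.std(x ** k, ddof=1) / np.sqrt(x.size)
            assert abs(mk - np.mean(x ** k)) < 3 * se

    @pytest.mark.parametrize("theta", [-3.0, -0.5, 1.5, 3.0])
    def test_series_representation_agrees(self, theta):
        g = TLG(theta, weibull_parent(2.0, 2.0))
        for k in (1, 2, 3):
            assert g.series_moment(k, order=40) == pytest.approx(
                g.moment(k), abs=1e-6)

    def test_series_pdf_agrees(self, tlg_weibull):
        xs = np.linspace(0.2, 4.5, 12)
        assert np.allclose(tlg_weibull.series_pdf(xs, order=40),
                           tlg_weibull.pdf(xs), atol=1e-12)

    def test_series_tail_bound_reported(self, tlg_weibull):
        coef = tlg_weibull.series_coefficients(order=40)
        assert coef.nu.shape == (41,)
        assert coef.tail_bound < 1e-30
        # |nu_i| eventually decreasing
        mags = np.abs(coef.nu[5:])
        assert np.all(np.diff(mags) <= 0)


class TestMgf:
    def test_at_zero(self, tlg_weibull):
        assert tlg_weibull.mgf(0.0) == 1.0

    def test_derivatives_match_moments(self, tlg_weibull):
        eps = 1e-5
        d1 = (tlg_weibull.mgf(eps) - tlg_weibull.mgf(-eps)) / (2 * eps)
        d2 = (tlg_weibull.mgf(eps) - 2 + tlg_weibull.mgf(-eps)) / eps ** 2
        assert d1 == pytest.approx(tlg_weibull.moment(1), rel=1e-5)
        assert d2 == pytest.approx(tlg_weibull.moment(2), rel=1e-4)


class TestMeanDeviations:
    def test_nonnegative_and_match_direct_quadrature(self, tlg_weibull):
        d1, d2 = tlg_weibull.mean_deviations()
        assert d1 >= 0 and d2 >= 0
        mu = tlg_weibull.moment(1)
        med = tlg_weibull.ppf(0.5)
        q1, _ = integrate.quad(lambda t: abs(t - mu) * tlg_weibull.pdf(t),
                               0, np.inf, limit=300)
        q2, _ = integrate.quad(lambda t: abs(t - med) * tlg_weibull.pdf(t),
                               0, np.inf, limit=300)
        assert d1 == pytest.approx(q1, abs=1e-7)
        assert d2 == pytest.approx(q2, abs=1e-7)

    def test_median_deviation_matches_monte_carlo(self, tlg_weibull):
        _, d2 = tlg_weibull.mean_deviations()
        x = tlg_weibull.rvs(200_000, rng=3)
        med = tlg_weibull.ppf(0.5)
        sample = np.abs(x - med)
        se = sample.std(ddof=1) / np.sqrt(x.size)
        assert abs(d2 - sample.mean()) < 3 * se


class TestEntropies:
    def test_shannon_matches_direct_quadrature(self, tlg_weibull):
        direct, _ = integrate.quad(
            lambda t: -tlg_weibull.pdf(t) * tlg_weibull.logpdf(t),
            1e-9, 40, limit=300)
        assert tlg_weibull.shannon_entropy() == pytest.approx(direct, abs=1e-7)

    def test_uniform_parent_reduces_to_unit_entropy(self):
        g = TLG(1.0, uniform_parent())
        direct, _ = integrate.quad(
            lambda t: -utl_pdf(t, 1.0) * np.log(utl_pdf(t, 1.0)), 0, 1)
        assert g.shannon_entropy() == pytest.approx(direct, abs=1e-9)

    def test_scale_equivariance(self):
        # doubling the parent scale shifts the entropy by log 2
        h1 = TLG(0.5, weibull_parent(2.0, 2.0)).shannon_entropy()
        h2 = TLG(0.5, weibull_parent(2.0, 4.0)).shannon_entropy()
        assert h2 - h1 == pytest.approx(np.log(2.0), abs=1e-8)

    def test_closed_form_shortcut_is_approximate(self, tlg_weibull):
        # the shortcut treats G(X) as uniform; it should be close but is not
        # the exact value (the gap is the documented approximation error)
        exact = tlg_weibull.shannon_entropy()
        approx = tlg_weibull.shannon_entropy_closed_form()
        assert np.isfinite(approx)
        assert abs(approx - exact) < 0.1

    def test_renyi_matches_direct_quadrature(self, tlg_weibull):
        tau = 2.0
        val, _ = integrate.quad(lambda t: tlg_weibull.pdf(t) ** tau,
                                1e-9, 40, limit=300)
        assert tlg_weibull.renyi_entropy(tau) == pytest.approx(
            np.log(val) / (1 - tau), abs=1e-8)

    def test_renyi_uniform_parent_brute_force(self):
        g = TLG(1.0, uniform_parent())
        tau = 1.5
        val, _ = integrate.quad(lambda t: utl_pdf(t, 1.0) ** tau, 0, 1)
        assert g.renyi_entropy(tau) == pytest.approx(np.log(val) / (1 - tau),
                                                     abs=1e-10)

    def test_renyi_continuity_at_one(self, tlg_weibull):
        h = tlg_weibull.shannon_entropy()
        assert tlg_weibull.renyi_entropy(1 - 1e-3) == pytest.approx(h, abs=1e-3)
        assert tlg_weibull.renyi_entropy(1 + 1e-3) == pytest.approx(h, abs=1e-3)

    def test_renyi_rejects_bad_tau(self, tlg_weibull):
        with pytest.raises(ValueError):
            tlg_weibull.renyi_entropy(1.0)
        with pytest.raises(ValueError):
            tlg_weibull.renyi_entropy(-0.5)
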