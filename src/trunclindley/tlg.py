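"""Truncated Lindley-G family: composition of the unit law with a parent G.

The family cdf is ``F(x) = F_UTL(G(x))`` with density

    f(x) = theta**2 * C(theta) * g(x) * (1 + G(x)) * exp(-theta * G(x)),

so every member is the parent law reweighted by the unit truncated Lindley
density in probability space.  The extra parameter theta tilts mass towards
the upper (theta < 0) or lower (theta > 0) end of the parent's range.

Moments, the moment generating function, mean deviations and entropies are
computed by adaptive quadrature in the probability scale ``y = G(x)``, where
the weight is exactly the UTL density: e.g. the k-th raw moment is
``int_0^1 Q_G(y)**k f_UTL(y) dy``.  An alternating exponentiated-G series
expansion of the density is provided purely as a cross-check (it converges
usefully only for moderate ``|theta|``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .parents import ParentModel, uniform_parent
from .utl import (
    _log_theta2_C,
    _validate_theta,
    utl_cdf,
    utl_logpdf,
    utl_pdf,
    utl_ppf,
)

__all__ = ["TLG", "SeriesCoefficients"]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=400)


@dataclass(frozen=True)
class SeriesCoefficients:
    """Coefficients nu_i = (-1)**(i+1) theta**i / i! of the exponentiated-G
    expansion of the family density, truncated at ``order``.

    ``tail_bound`` is the magnitude of the first omitted coefficient scaled
    by the largest bracket factor, a heuristic for the truncation error of
    the alternating series (tight only once the terms decrease).
    """

    theta: float
    order: int
    nu: np.ndarray
    tail_bound: float

    @classmethod
    def build(cls, theta: float, order: int) -> "SeriesCoefficients":
        i = np.arange(order + 1)
        nu = (-1.0) ** (i + 1) * theta ** i / special.factorial(i)
        nxt = abs(theta) ** (order + 1) / math.factorial(order + 1)
        tail = nxt * (abs(theta + 1.0) + abs(theta)) * (order + 2)
        return cls(theta=theta, order=order, nu=nu, tail_bound=float(tail))


class TLG:
    """Truncated Lindley-G distribution with shape ``theta`` and parent G."""

    def __init__(self, theta: float, parent: ParentModel):
        self.theta = _validate_theta(theta)
        self.parent = parent

    # -- distribution functions ------------------------------------------
    def cdf(self, x):
        return utl_cdf(self.parent.cdf(x), self.theta)

    def sf(self, x):
        return 1.0 - self.cdf(x)

    def logpdf(self, x):
        G = np.asarray(self.parent.cdf(x), dtype=float)
        return (_log_theta2_C(self.theta) + self.parent.logpdf(x)
                + np.log1p(G) - self.theta * G)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def ppf(self, u):
        return self.parent.ppf(utl_ppf(u, self.theta))

    def rvs(self, n: int, rng=None):
        rng = np.random.default_rng(rng)
        return self.ppf(rng.uniform(size=n))

    # -- quadrature in the probability scale -----------------------------
    def _expect(self, fn, lo: float = 0.0, hi: float = 1.0, **kw):
        """int_lo^hi fn(y) f_UTL(y) dy with the stable unit-law density."""
        theta = self.theta
        val, err = integrate.quad(
            lambda y: fn(y) * utl_pdf(y, theta), lo, hi, **{**_QUAD_KW, **kw}
        )
        return val, err

    def moment(self, k: int, return_error: bool = False):
        """k-th raw moment by quadrature; ``nan`` if the integral diverges."""
        if k == 0:
            return (1.0, 0.0) if return_error else 1.0
        Q = self.parent.ppf
        with np.errstate(over="ignore"):
            val, err = self._expect(lambda y: Q(y) ** k)
        if not np.isfinite(val):
            val = float("nan")
        return (val, err) if return_error else val

    def mgf(self, t: float):
        """Moment generating function E[exp(tX)]; inf/nan flags divergence."""
        if t == 0.0:
            return 1.0
        Q = self.parent.ppf
        with np.errstate(over="ignore"):
            val, _ = self._expect(lambda y: np.exp(t * Q(y)))
        return val

    def incomplete_moment(self, t: float, k: int = 1) -> float:
        """int_{-inf}^{t} x**k f(x) dx, via the probability scale."""
        yt = float(self.parent.cdf(t))
        if yt <= 0.0:
            return 0.0
        Q = self.parent.ppf
        val, _ = self._expect(lambda y: Q(y) ** k, 0.0, yt)
        return val

    def mean_deviations(self):
        """(delta1, delta2): mean absolute deviations about mean and median.

        delta1 = 2 mu F(mu) - 2 J(mu),  delta2 = mu - 2 J(M),
        with J(t) the first incomplete moment and M the median.
        """
        mu = self.moment(1)
        if not np.isfinite(mu):
            raise ValueError("mean deviations undefined: first moment diverges")
        med = self.ppf(0.5)
        d1 = 2.0 * mu * float(self.cdf(mu)) - 2.0 * self.incomplete_moment(mu)
        d2 = mu - 2.0 * self.incomplete_moment(med)
        return float(d1), float(d2)

    # -- entropies --------------------------------------------------------
    def renyi_entropy(self, tau: float) -> float:
        """Renyi entropy (1/(1-tau)) log int f**tau, tau > 0, tau != 1."""
        if tau <= 0 or tau == 1.0:
            raise ValueError("tau must be positive and different from 1")
        a, b = self.parent.support
        with np.errstate(over="ignore"):
            val, _ = integrate.quad(
                lambda x: np.exp(tau * self.logpdf(x)), a, b, **_QUAD_KW
            )
        if not np.isfinite(val) or val <= 0:
            return float("nan")
        return float(np.log(val) / (1.0 - tau))

    def shannon_entropy(self) -> float:
        """Exact differential entropy -E[log f(X)], by quadrature in y=G(x).

        log f(x) decomposes as log g(Q_G(y)) + log f_UTL(y), so the entropy
        is the expectation of minus that sum under the unit law.
        """
        theta = self.theta
        Q = self.parent.ppf
        lg = self.parent.logpdf

        def integrand(y):
            return -(lg(Q(y)) + utl_logpdf(y, theta))

        val, _ = self._expect(integrand)
        return float(val)

    def shannon_entropy_closed_form(self) -> float:
        """Closed-form entropy shortcut  -log(theta^2 C) + eta_G + 1 - 2 log 2
        + theta/2.

        This shortcut treats G(X) as uniform on (0, 1); under this family
        G(X) actually follows the unit truncated Lindley law, so the value is
        only an approximation to :meth:`shannon_entropy` (exact in the
        theta -> 0 limit).  Both are exposed so the gap can be inspected.
        """
        if self.parent.entropy is None:
            raise ValueError("parent entropy unknown; no closed form available")
        return float(
            -_log_theta2_C(self.theta) + self.parent.entropy
            + 1.0 - 2.0 * np.log(2.0) + self.theta / 2.0
        )

    # -- exponentiated-G series cross-checks ------------------------------
    def series_coefficients(self, order: int = 40) -> SeriesCoefficients:
        return SeriesCoefficients.build(self.theta, order)

    def series_pdf(self, x, order: int = 40):
        """Density from the exponentiated-G expansion (cross-check only)."""
        theta = self.theta
        coef = self.series_coefficients(order)
        x = np.asarray(x, dtype=float)
        G = np.asarray(self.parent.cdf(x), dtype=float)
        g = np.asarray(self.parent.pdf(x), dtype=float)
        out = np.zeros_like(G)
        C = np.exp(_log_theta2_C(theta)) / theta ** 2
        for i, nu in enumerate(coef.nu):
            h_i = i * g * G ** (i - 1) if i >= 1 else 0.0
            h_ip1 = (i + 1) * g * G ** i
            out += nu * ((theta + 1.0) * h_i + theta * h_ip1)
        return C * out

    def series_moment(self, r: int, order: int = 40) -> float:
        """r-th raw moment from the exponentiated-G expansion.

        Uses E[Y_j^r] = j * int_0^1 Q_G(u)^r u^(j-1) du for the power-j
        exponentiated-G variate Y_j.
        """
        theta = self.theta
        coef = self.series_coefficients(order)
        Q = self.parent.ppf
        C = np.exp(_log_theta2_C(theta)) / theta ** 2

        def eg_moment(j: int) -> float:
            if j == 0:
                return 0.0
            val, _ = integrate.quad(
                lambda u: Q(u) ** r * j * u ** (j - 1), 0.0, 1.0, **_QUAD_KW
            )
            return val

        eg = [eg_moment(j) for j in range(order + 2)]
        total = sum(
            nu * ((theta + 1.0) * eg[i] + theta * eg[i + 1])
            for i, nu in enumerate(coef.nu)
        )
        return float(C * total)


def uniform_tlg(theta: float) -> TLG:
    """The composition with a standard uniform parent (reduces to the unit law)."""
    return TLG(theta, uniform_parent())
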