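"""Unit truncated Lindley (UTL) distribution on [0, 1].

The UTL law is the one-parameter Lindley distribution truncated to the unit
interval and renormalised:

    F(x) = C(theta) * [1 + theta - (1 + theta + theta*x) * exp(-theta*x)]
    f(x) = theta**2 * C(theta) * (1 + x) * exp(-theta*x),      0 <= x <= 1,

with normalising constant ``C(theta) = 1 / D(theta)`` where

    D(theta) = 1 + theta - exp(-theta) - 2*theta*exp(-theta).

``theta`` is any nonzero real; ``D(theta) > 0`` on both half-lines.  As
``theta -> 0`` the density degenerates continuously to ``2*(1 + x)/3``
(``D ~ (3/2) theta**2``), and every routine here is guarded so that the limit
is reached without catastrophic cancellation.  Large negative ``theta`` (the
regime favoured by real lifetime data fits, where the mass piles up near
``x = 1``) is handled by a scaled form that never exponentiates ``-theta``
on its own.

The quantile function inverts F in closed form through the Lambert W
function: the defining equation rearranges to ``w * exp(w)`` form with
``w = -(1 + theta + theta*x)``, which selects the ``-1`` branch for
``theta > 0`` (where ``w < -1``) and the principal branch for ``theta < 0``.
A bracketed Brent solve backs up the closed form wherever the branch
arithmetic is ill-conditioned (tiny ``|theta|``, overflowing arguments).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special

__all__ = [
    "log_norm_const",
    "utl_cdf",
    "utl_pdf",
    "utl_logpdf",
    "utl_ppf",
    "utl_rvs",
]

# Below this, D(theta) is evaluated from its power series; the closed form
# loses all significant digits because D ~ (3/2) theta**2.
_SERIES_THETA = 0.05
# Below this (scaled form), exp(-theta) alone would dwarf every other term.
_NEG_SCALED_THETA = -30.0
# Quantile: |theta| below this routes straight to Brent (the Lambert argument
# collides with the branch point -1/e and loses precision).
_PPF_BRENT_THETA = 1e-2


def _validate_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta) or theta == 0.0:
        raise ValueError("theta must be a finite nonzero real number")
    return theta


def _series_logD_terms(theta: float, nmax: int = 14) -> float:
    """D(theta) summed from D = sum_{n>=2} (-1)^n (2n-1) theta^n / n!."""
    n = np.arange(2, nmax + 1)
    terms = ((-1.0) ** n) * (2 * n - 1) / special.factorial(n) * theta ** n
    return float(terms.sum())


def _logD(theta: float) -> float:
    """log D(theta), stable over the whole punctured real line."""
    if theta <= _NEG_SCALED_THETA:
        # D * e^theta = (1+theta) e^theta - (1+2 theta)  (all terms moderate)
        return -theta + np.log((1.0 + theta) * np.exp(theta) - (1.0 + 2.0 * theta))
    if abs(theta) < _SERIES_THETA:
        return np.log(_series_logD_terms(theta))
    u = np.expm1(-theta)
    return np.log(-(u + theta) - 2.0 * theta * u)


def _logDexp(theta: float) -> float:
    """log( D(theta) * exp(theta) ), the scale-free denominator."""
    if theta <= _NEG_SCALED_THETA:
        return np.log((1.0 + theta) * np.exp(theta) - (1.0 + 2.0 * theta))
    return theta + _logD(theta)


def _log_theta2_C(theta: float) -> float:
    """log( theta**2 * C(theta) ) = 2 log|theta| - log D(theta).

    Finite in the theta -> 0 limit (value log(2/3)); the series branch
    evaluates the ratio theta**2 / D directly.
    """
    if abs(theta) < _SERIES_THETA:
        # theta^2 / D = (2/3) / (1 + c1 th + c2 th^2 + ...)
        n = np.arange(3, 15)
        corr = ((-1.0) ** n) * (2 * n - 1) / special.factorial(n) * theta ** (n - 2)
        return np.log(2.0 / 3.0) - np.log1p(float(corr.sum()) / 1.5)
    return 2.0 * np.log(abs(theta)) - _logD(theta)


def _dlogD(theta: float) -> float:
    """d/dtheta log D(theta) = D'(theta) / D(theta)."""
    if theta <= _NEG_SCALED_THETA:
        # D' e^theta = e^theta - 1 + 2 theta
        return (np.exp(theta) - 1.0 + 2.0 * theta) / np.exp(_logDexp(theta))
    if abs(theta) < _SERIES_THETA:
        return 2.0 / theta - _dlog_theta2_C(theta)
    u = np.expm1(-theta)
    D = -(u + theta) - 2.0 * theta * u
    Dp = 2.0 * theta + u * (2.0 * theta - 1.0)
    return Dp / D

def _dlog_theta2_C(theta: float) -> float:
    """d/dtheta log(theta**2 C) = 2/theta - D'/D; finite through theta = 0."""
    if abs(theta) < _SERIES_THETA:
        # 2/theta - D'/D = (2 D - theta D') / (theta D); the n=2 terms cancel:
        # 2 D - theta D' = sum_{n>=3} (-1)^n (2n-1)(2-n) theta^n / n!
        n = np.arange(3, 15)
        num = (((-1.0) ** n) * (2 * n - 1) * (2.0 - n) / special.factorial(n)
               * theta ** (n - 1)).sum()
        return float(num) / _series_logD_terms(theta)
    return 2.0 / theta - _dlogD(theta)


def log_norm_const(theta: float) -> float:
    """log C(theta) = -log(1 + theta - exp(-theta) - 2 theta exp(-theta)).

    Raises ``ValueError`` at theta = 0, where the distribution itself is
    defined only as a limit.
    """
    theta = _validate_theta(theta)
    return -_logD(theta)


def _check_unit_interval(x: np.ndarray) -> None:
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError("x must lie in the unit interval [0, 1]")


def utl_cdf(x, theta: float):
    """CDF of the unit truncated Lindley law, elementwise in ``x``."""
    theta = _validate_theta(theta)
    x = np.asarray(x, dtype=float)
    _check_unit_interval(x)
    if theta <= _NEG_SCALED_THETA:
        # scale numerator and denominator by e^theta
        denom = (1.0 + theta) * np.exp(theta) - (1.0 + 2.0 * theta)
        num = ((1.0 + theta) * np.exp(theta)
               - (1.0 + theta + theta * x) * np.exp(theta * (1.0 - x)))
        out = num / denom
    else:
        # N(x) = 1+theta-(1+theta+theta x) e^{-theta x}, rewritten so that the
        # O(1) pieces cancel analytically:  N = -(expm1(-t x)+t x) - t(1+x) expm1(-t x)
        u = np.expm1(-theta * x)
        num = -(u + theta * x) - theta * (1.0 + x) * u
        out = num / np.exp(_logD(theta))
    return np.clip(out, 0.0, 1.0)[()] if out.ndim == 0 else np.clip(out, 0.0, 1.0)


def utl_logpdf(x, theta: float):
    """log density; computed as log(theta^2 C) + log1p(x) - theta*x."""
    theta = _validate_theta(theta)
    x = np.asarray(x, dtype=float)
    _check_unit_interval(x)
    out = _log_theta2_C(theta) + np.log1p(x) - theta * x
    return out[()] if out.ndim == 0 else out


def utl_pdf(x, theta: float):
    return np.exp(utl_logpdf(x, theta))


def _ppf_brent(u: np.ndarray, theta: float) -> np.ndarray:
    out = np.empty_like(u)
    for i, ui in np.ndenumerate(u):
        out[i] = optimize.brentq(
            lambda t: utl_cdf(t, theta) - ui, 0.0, 1.0, xtol=1e-15, rtol=1e-15
        )
    return out


def utl_ppf(u, theta: float):
    """Quantile function, by Lambert-W inversion with a Brent safety net.

    The closed form is ``y = -1 - 1/theta - W_b((u/C - theta - 1) e^{-theta-1})
    / theta`` with branch ``b = -1`` for ``theta > 0`` and the principal
    branch for ``theta < 0``.  A single Newton polish step in the stable cdf
    tightens the result to ~1e-12; any point whose branch arithmetic lands
    outside [0, 1] falls back to bracketed root finding (with a warning).
    """
    theta = _validate_theta(theta)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")

    if abs(theta) < _PPF_BRENT_THETA:
        y = _ppf_brent(u, theta)
        return y[0] if scalar else y

    logD = _logD(theta)
    # Lambert argument (u*D - theta - 1) * exp(-theta - 1), in log space when
    # the factors are huge (very negative theta).
    if theta < -1.0:
        log_arg = np.logaddexp(np.log(u) + logD, np.log(-theta - 1.0)) - theta - 1.0
        if np.max(log_arg) > 700.0:  # would overflow double: Brent instead
            y = _ppf_brent(u, theta)
            return y[0] if scalar else y
        arg = np.exp(log_arg)
    else:
        arg = (u * np.exp(logD) - theta - 1.0) * np.exp(-theta - 1.0)

    branch = -1 if theta > 0 else 0
    with np.errstate(invalid="ignore"):
        w = special.lambertw(arg, k=branch).real
    y = -1.0 - 1.0 / theta - w / theta

    bad = ~np.isfinite(y) | (y < -1e-8) | (y > 1.0 + 1e-8)
    y = np.clip(y, 0.0, 1.0)
    ok = ~bad
    if np.any(ok):
        # one Newton step on the stable cdf
        f = utl_pdf(y[ok], theta)
        step = (utl_cdf(y[ok], theta) - u[ok]) / np.where(f > 1e-300, f, np.inf)
        y[ok] = np.clip(y[ok] - step, 0.0, 1.0)
    if np.any(bad):
        warnings.warn(
            "Lambert-W inversion left the unit interval for "
            f"{int(bad.sum())} point(s); falling back to bracketed root finding",
            RuntimeWarning,
            stacklevel=2,
        )
        y[bad] = _ppf_brent(u[bad], theta)
    return y[0] if scalar else y


def utl_rvs(n: int, theta: float, rng=None):
    """Inverse-transform sample of size ``n`` (``rng``: seed or Generator)."""
    rng = np.random.default_rng(rng)
    return utl_ppf(rng.uniform(size=n), theta)
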