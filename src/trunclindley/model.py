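"""Maximum-likelihood fitting of the TLW and baseline Weibull models.

Follows the statsmodels pattern: a model object is built from the data,
``fit()`` runs the optimisation and returns a :class:`FitResult` carrying
estimates, standard errors, the maximised log-likelihood and the
information-criteria block (AIC / CAIC / BIC / HQIC).

The TLW log-likelihood for an i.i.d. positive sample, with
``z_i = (x_i/lam)**k``, is

    l = n [2 log|theta| + log C(theta) + log k - k log lam]
        + (k-1) sum log x_i + sum log(2 - e^{-z_i}) - sum z_i
        - theta sum (1 - e^{-z_i}).

The surface is optimised in (theta, log k, log lam) with the analytic score;
it is typically bimodal across the sign of theta, so the multistart bank
covers both half-lines (theta in +-{0.5, 2, 10, 40} by default, with (k,
lam) seeded from the Weibull baseline fit).  The likelihood extends
continuously through theta = 0 (the series guard in the unit-law constants
makes the objective smooth there), so the optimiser may travel between the
half-lines freely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from statsmodels.tools import numdiff

from .utl import _dlog_theta2_C, _log_theta2_C, _validate_theta

__all__ = [
    "tlw_loglik",
    "tlw_score",
    "information_criteria",
    "FitResult",
    "TLWModel",
    "WeibullModel",
]

_DEFAULT_THETA_STARTS = (-40.0, -10.0, -2.0, -0.5, 0.5, 2.0, 10.0, 40.0)


def information_criteria(loglik: float, n: int, p: int) -> Dict[str, float]:
    """AIC, corrected AIC, BIC and Hannan-Quinn from (l, n, p).

    AIC = -2l + 2p;  CAIC = AIC + 2p(p+1)/(n-p-1);  BIC = -2l + p log n;
    HQIC = -2l + 2p log(log n).
    """
    if n <= p + 1:
        raise ValueError("information criteria require n > p + 1")
    aic = -2.0 * loglik + 2.0 * p
    return {
        "aic": aic,
        "caic": aic + 2.0 * p * (p + 1.0) / (n - p - 1.0),
        "bic": -2.0 * loglik + p * np.log(n),
        "hqic": -2.0 * loglik + 2.0 * p * np.log(np.log(n)),
    }


def _prepare_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0 or np.any(~np.isfinite(x)) or np.any(x <= 0.0):
        raise ValueError("sample must be finite and strictly positive")
    return x


def tlw_loglik(x, theta: float, k: float, lam: float) -> float:
    """TLW log-likelihood of an uncensored sample at (theta, k, lam)."""
    x = _prepare_sample(x)
    theta = _validate_theta(theta)
    n = x.size
    logz = np.clip(k * (np.log(x) - np.log(lam)), -745.0, 690.0)
    z = np.exp(logz)
    E = np.exp(-z)
    return float(
        n * (_log_theta2_C(theta) + np.log(k) - k * np.log(lam))
        + (k - 1.0) * np.log(x).sum()
        + np.log(2.0 - E).sum()
        - z.sum()
        - theta * (1.0 - E).sum()
    )


def _score_parts(x, theta, k, lam):
    """Per-observation score contributions wrt (theta, k, lam)."""
    x = _prepare_sample(x)
    logz = np.clip(k * (np.log(x) - np.log(lam)), -745.0, 690.0)
    z = np.exp(logz)
    E = np.exp(-z)
    w = -1.0 + E / (2.0 - E) - theta * E  # d log f / d z
    lx = np.log(x / lam)
    d_theta = _dlog_theta2_C(theta) - (1.0 - E)
    d_k = 1.0 / k - np.log(lam) + np.log(x) + w * z * lx
    d_lam = -k / lam - (k / lam) * w * z
    return d_theta, d_k, d_lam


def tlw_score(x, theta: float, k: float, lam: float) -> np.ndarray:
    """Analytic score vector (dl/dtheta, dl/dk, dl/dlam)."""
    theta = _validate_theta(theta)
    d_theta, d_k, d_lam = _score_parts(x, theta, k, lam)
    return np.array([np.sum(d_theta), np.sum(d_k), np.sum(d_lam)])


def tlw_score_obs(x, theta: float, k: float, lam: float) -> np.ndarray:
    """n x 3 matrix of per-observation scores (for the OPG fallback)."""
    theta = _validate_theta(theta)
    parts = _score_parts(x, theta, k, lam)
    return np.column_stack([np.broadcast_to(p, np.shape(parts[1])) for p in parts])


@dataclass
class FitResult:
    """Container for a maximum-likelihood fit.

    ``params`` maps parameter names to estimates; ``se`` and ``ci95`` follow
    the same ordering.  ``criteria`` holds AIC/CAIC/BIC/HQIC; ``best_start``
    records the start that won the multistart race.
    """

    param_names: List[str]
    params: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_starts: int = 1
    best_start: Optional[dict] = None
    se_method: str = "hessian"
    model: str = ""

    @property
    def p(self) -> int:
        return len(self.param_names)

    @property
    def ci95(self) -> np.ndarray:
        return np.column_stack([self.params - 1.96 * self.se,
                                self.params + 1.96 * self.se])

    @property
    def criteria(self) -> Dict[str, float]:
        return information_criteria(self.loglik, self.n, self.p)

    @property
    def aic(self) -> float:
        return self.criteria["aic"]

    @property
    def bic(self) -> float:
        return self.criteria["bic"]

    def params_dict(self) -> Dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))

    def summary(self) -> str:
        crit = self.criteria
        lines = [
            f"{self.model} maximum-likelihood fit (n = {self.n})",
            f"  log-likelihood = {self.loglik:.4f}   converged = {self.converged}"
            f"   starts = {self.n_starts}   se = {self.se_method}",
            f"  AIC = {crit['aic']:.3f}  CAIC = {crit['caic']:.3f}"
            f"  BIC = {crit['bic']:.3f}  HQIC = {crit['hqic']:.3f}",
            f"  {'param':>8} {'estimate':>12} {'std.err':>10} "
            f"{'[0.025':>10} {'0.975]':>10}",
        ]
        for name, est, se, (lo, hi) in zip(
            self.param_names, self.params, self.se, self.ci95
        ):
            lines.append(f"  {name:>8} {est:12.5f} {se:10.4f} {lo:10.4f} {hi:10.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "params": self.params_dict(),
                "se": dict(zip(self.param_names, map(float, self.se))),
                "ci95": {
                    nm: [float(lo), float(hi)]
                    for nm, (lo, hi) in zip(self.param_names, self.ci95)
                },
                "loglik": self.loglik,
                "n": self.n,
                "criteria": self.criteria,
                "converged": self.converged,
                "se_method": self.se_method,
            },
            indent=2,
        )


class WeibullModel:
    """Two-parameter Weibull baseline, fitted by profile maximum likelihood.

    The scale profiles out in closed form, ``lam(k) = mean(x**k) ** (1/k)``,
    leaving a well-behaved one-dimensional score equation in k.
    """

    def __init__(self, endog):
        self.endog = _prepare_sample(endog)
        if self.endog.size < 3:
            raise ValueError("need at least 3 observations")

    def loglike(self, k: float, lam: float) -> float:
        x = self.endog
        z = (x / lam) ** k
        return float(x.size * (np.log(k) - k * np.log(lam))
                     + (k - 1.0) * np.log(x).sum() - z.sum())

    def _profile_score(self, k: float) -> float:
        # dl/dk after substituting the closed-form lam(k)
        x = self.endog
        lx = np.log(x)
        xk = x ** k
        return float(1.0 / k + lx.mean() - (xk * lx).sum() / xk.sum())

    def fit(self) -> FitResult:
        lo, hi = 1e-3, 1.0
        while self._profile_score(hi) > 0 and hi < 1e4:
            hi *= 2.0
        k = optimize.brentq(self._profile_score, lo, hi, xtol=1e-12)
        lam = float(np.mean(self.endog ** k) ** (1.0 / k))
        ll = self.loglike(k, lam)
        nll = lambda p: -self.loglike(p[0], p[1])
        H = numdiff.approx_hess([k, lam], nll)
        se, method = _se_from_hessian(H)
        return FitResult(
            param_names=["k", "lam"],
            params=np.array([k, lam]),
            se=se,
            loglik=ll,
            n=self.endog.size,
            converged=True,
            se_method=method,
            model="Weibull",
        )


def _se_from_hessian(H: np.ndarray, opg: Optional[np.ndarray] = None):
    """Standard errors from the observed information; OPG fallback."""
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.all(diag > 0):
            return np.sqrt(diag), "hessian"
    except np.linalg.LinAlgError:
        pass
    if opg is not None:
        try:
            cov = np.linalg.inv(opg)
            diag = np.diag(cov)
            if np.all(diag > 0):
                return np.sqrt(diag), "opg"
        except np.linalg.LinAlgError:
            pass
    return np.full(H.shape[0], np.nan), "failed"


class TLWModel:
    """Truncated Lindley-Weibull model for an uncensored positive sample."""

    def __init__(self, endog):
        self.endog = _prepare_sample(endog)
        if self.endog.size < 5:
            raise ValueError("need at least 5 observations")

    # objective in (theta, log k, log lam)
    def _negloglik(self, p: np.ndarray) -> float:
        theta, logk, loglam = p
        if not np.all(np.isfinite(p)) or abs(logk) > 30 or abs(loglam) > 300:
            return 1e300
        k, lam = np.exp(logk), np.exp(loglam)
        if theta == 0.0:
            theta = 1e-300  # continuous limit; guard the formal exclusion
        ll = tlw_loglik(self.endog, theta, k, lam)
        return -ll if np.isfinite(ll) else 1e300

    def _neggrad(self, p: np.ndarray) -> np.ndarray:
        theta, logk, loglam = p
        if not np.all(np.isfinite(p)) or abs(logk) > 30 or abs(loglam) > 300:
            return np.zeros(3)
        k, lam = np.exp(logk), np.exp(loglam)
        if theta == 0.0:
            theta = 1e-300
        with np.errstate(over="ignore", invalid="ignore"):
            g = tlw_score(self.endog, theta, k, lam)
            out = -np.array([g[0], g[1] * k, g[2] * lam])
        return np.where(np.isfinite(out), out, 0.0)

    def loglike(self, theta: float, k: float, lam: float) -> float:
        return tlw_loglik(self.endog, theta, k, lam)

    def fit(
        self,
        theta_starts: Sequence[float] = _DEFAULT_THETA_STARTS,
        extra_starts: Optional[Sequence[Tuple[float, float, float]]] = None,
        tol: float = 1e-12,
    ) -> FitResult:
        """Multistart quasi-Newton maximisation.

        Each start pairs a theta from the bank with (k, lam) from the
        Weibull baseline fit; ``extra_starts`` may add full (theta, k, lam)
        triples.  Raises ``RuntimeError`` if every start fails.
        """
        wb = WeibullModel(self.endog).fit()
        k0, lam0 = wb.params
        starts = [(th, k0, lam0) for th in theta_starts]
        if extra_starts:
            starts += [tuple(map(float, s)) for s in extra_starts]

        best, log = None, []
        for th, k_s, l_s in starts:
            p0 = np.array([th, np.log(k_s), np.log(l_s)])
            try:
                r = optimize.minimize(
                    self._negloglik, p0, jac=self._neggrad, method="L-BFGS-B",
                    options=dict(maxiter=500, ftol=tol, gtol=1e-10),
                )
            except Exception as exc:  # pragma: no cover - defensive
                log.append({"start": [th, k_s, l_s], "error": str(exc)})
                continue
            log.append({"start": [th, k_s, l_s], "fun": float(r.fun),
                        "success": bool(r.success)})
            if np.isfinite(r.fun) and (best is None or r.fun < best.fun):
                best, best_start = r, log[-1]
        if best is None or best.fun >= 1e299:
            raise RuntimeError(f"all starts failed to converge: {log}")

        theta = float(best.x[0])
        k, lam = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
        ll = -float(best.fun)
        nll = lambda q: -tlw_loglik(self.endog, q[0], q[1], q[2])
        H = numdiff.approx_hess(np.array([theta, k, lam]), nll)
        opg = tlw_score_obs(self.endog, theta, k, lam)
        se, method = _se_from_hessian(H, opg.T @ opg)
        grad_norm = float(np.linalg.norm(self._neggrad(best.x)))
        return FitResult(
            param_names=["theta", "k", "lam"],
            params=np.array([theta, k, lam]),
            se=se,
            loglik=ll,
            n=self.endog.size,
            converged=bool(best.success) and grad_norm < 1e-3 * (1 + abs(ll)),
            n_starts=len(starts),
            best_start=best_start,
            se_method=method,
            model="TLW",
        )
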