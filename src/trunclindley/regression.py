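"""TLW survival regression with censoring and two log-link components.

Both Weibull parameters carry their own systematic component,

    lam_i = exp(v_i' beta_scale),     k_i = exp(v_i' beta_shape),

while the tilt parameter theta is shared across observations.  For observed
failure times (delta_i = 1) the likelihood contribution is the TLW density;
for right-censored times (delta_i = 0) it is the survival function

    S(x | v) = 1 - C(theta) [1 + theta - (1 + theta + w) e^{-w}],
    w(x | v) = theta (1 - exp(-(x / lam_i)^{k_i})).

Fitting maximises the total log-likelihood over (theta, beta_scale,
beta_shape) by multistart quasi-Newton with the analytic gradient; standard
errors come from the numeric Hessian and Wald p-values use the standard
normal reference.

Residual diagnostics: martingale residuals ``r_M = delta + log S(x | v)``,
their signed square-root deviance transform, and (for fully observed data)
normal quantile residuals ``Phi^{-1}(F(x | v))``.  A plain product-limit
(Kaplan-Meier) estimator is included for overlay plots and group summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .model import FitResult, _se_from_hessian
from .utl import _dlog_theta2_C, _dlogD, _log_theta2_C, _logDexp, _validate_theta
from .tlw import tlw_logpdf, tlw_logsf

__all__ = [
    "CensoredData",
    "TLWRegression",
    "WeibullRegression",
    "RegressionResults",
    "kaplan_meier",
]


@dataclass(frozen=True)
class CensoredData:
    """Right-censored sample: times, event indicators, and design matrices.

    ``exog_scale`` and ``exog_shape`` are the (intercept-including) design
    matrices of the two systematic components.
    """

    time: np.ndarray
    event: np.ndarray
    exog_scale: np.ndarray
    exog_shape: np.ndarray
    scale_names: Tuple[str, ...]
    shape_names: Tuple[str, ...]

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def build(cls, time, event, exog_scale, exog_shape=None,
              scale_names=None, shape_names=None) -> "CensoredData":
        time = np.asarray(time, dtype=float).ravel()
        event = np.asarray(event).ravel().astype(int)
        if np.any(time <= 0):
            raise ValueError("times must be strictly positive")
        if not set(np.unique(event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        Vs = np.atleast_2d(np.asarray(exog_scale, dtype=float))
        if Vs.shape[0] != time.size:
            Vs = Vs.T
        Vk = Vs if exog_shape is None else np.atleast_2d(np.asarray(exog_shape, float))
        if Vk.shape[0] != time.size:
            Vk = Vk.T
        for V, which in ((Vs, "scale"), (Vk, "shape")):
            if np.linalg.matrix_rank(V) < V.shape[1]:
                bad = _deficient_columns(V)
                raise ValueError(
                    f"{which} design matrix is rank deficient (columns {bad})"
                )
        sn = tuple(scale_names or [f"x{j}" for j in range(Vs.shape[1])])
        kn = tuple(shape_names or [f"x{j}" for j in range(Vk.shape[1])])
        return cls(time, event, Vs, Vk, sn, kn)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time: str = "time",
                       event: str = "event",
                       scale_covariates: Sequence[str] = (),
                       shape_covariates: Optional[Sequence[str]] = None,
                       add_intercept: bool = True) -> "CensoredData":
        def design(cols):
            mats = [np.ones(len(df))] if add_intercept else []
            names = ["intercept"] if add_intercept else []
            for c in cols:
                mats.append(df[c].to_numpy(dtype=float))
                names.append(c)
            return np.column_stack(mats), names
        Vs, sn = design(scale_covariates)
        cols_k = scale_covariates if shape_covariates is None else shape_covariates
        Vk, kn = design(cols_k)
        return cls.build(df[time].to_numpy(float), df[event].to_numpy(),
                         Vs, Vk, sn, kn)


def _deficient_columns(V: np.ndarray) -> List[int]:
    _, R = np.linalg.qr(V)
    d = np.abs(np.diag(R))
    return [int(j) for j in np.nonzero(d < 1e-10 * max(d.max(), 1.0))[0]]


def _links(data: CensoredData, beta_scale, beta_shape):
    lam = np.exp(np.clip(data.exog_scale @ beta_scale, -300, 300))
    k = np.exp(np.clip(data.exog_shape @ beta_shape, -30, 30))
    return lam, k


class TLWRegression:
    """TLW regression model for right-censored data."""

    family = "TLW"
    _has_theta = True

    def __init__(self, time, event, exog_scale, exog_shape=None,
                 scale_names=None, shape_names=None):
        if isinstance(time, CensoredData):
            self.data = time
        else:
            self.data = CensoredData.build(time, event, exog_scale, exog_shape,
                                           scale_names, shape_names)
        p = self.data.exog_scale.shape[1] + self.data.exog_shape.shape[1]
        if self.data.n <= p + 1:
            raise ValueError("too few observations for the requested design")

    @classmethod
    def from_dataframe(cls, df, **kw) -> "TLWRegression":
        return cls(CensoredData.from_dataframe(df, **kw), None, None)

    # -- parameter bookkeeping -------------------------------------------
    @property
    def param_names(self) -> List[str]:
        names = ["theta"] if self._has_theta else []
        names += [f"scale_{n}" for n in self.data.scale_names]
        names += [f"shape_{n}" for n in self.data.shape_names]
        return names

    def _split(self, params):
        p1 = self.data.exog_scale.shape[1]
        if self._has_theta:
            return params[0], params[1:1 + p1], params[1 + p1:]
        return None, params[:p1], params[p1:]

    # -- likelihood -------------------------------------------------------
    def loglike(self, params) -> float:
        theta, b1, b2 = self._split(np.asarray(params, float))
        lam, k = _links(self.data, b1, b2)
        d = self.data
        f_idx, c_idx = d.event == 1, d.event == 0
        ll = 0.0
        if f_idx.any():
            ll += tlw_logpdf(d.time[f_idx], theta, k[f_idx], lam[f_idx]).sum()
        if c_idx.any():
            ll += tlw_logsf(d.time[c_idx], theta, k[c_idx], lam[c_idx]).sum()
        return float(ll) if np.isfinite(ll) else -np.inf

    def score(self, params) -> np.ndarray:
        """Analytic gradient wrt (theta, beta_scale, beta_shape)."""
        theta, b1, b2 = self._split(np.asarray(params, float))
        theta = _validate_theta(theta)
        d = self.data
        lam, k = _links(d, b1, b2)
        x = d.time
        logz = np.clip(k * (np.log(x) - np.log(lam)), -745.0, 690.0)
        z = np.exp(logz)
        E = np.exp(-z)
        klx = k * (np.log(x) - np.log(lam))

        d_theta = np.empty(d.n)
        d_logk = np.empty(d.n)
        d_loglam = np.empty(d.n)

        f = d.event == 1
        if f.any():
            w = -1.0 + E[f] / (2.0 - E[f]) - theta * E[f]
            d_theta[f] = _dlog_theta2_C(theta) - (1.0 - E[f])
            d_logk[f] = 1.0 + klx[f] * (1.0 + w * z[f])
            d_loglam[f] = -k[f] * (1.0 + w * z[f])
        c = ~f
        if c.any():
            s = theta * E[c]
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                A = (1.0 + 2.0 * theta) * np.expm1(s) - s * np.exp(s)
                dA_dtheta = 2.0 * np.expm1(s) + np.exp(s) * (2.0 * theta - s) * E[c]
                dlogA_dz = -s * np.exp(s) * (2.0 * theta - s) / A
                dlogA_dtheta = dA_dtheta / A
            small = np.abs(s) < 1e-6
            dlogA_dtheta = np.where(small, 2.0 / theta, dlogA_dtheta)
            dlogA_dz = np.where(
                small, -np.exp(s) * (2.0 * theta - s) / (2.0 * theta), dlogA_dz
            )
            dlogDexp = 1.0 + _dlogD(theta)
            d_theta[c] = dlogA_dtheta - dlogDexp
            d_logk[c] = dlogA_dz * z[c] * klx[c]
            d_loglam[c] = -dlogA_dz * z[c] * k[c]

        g_theta = d_theta.sum()
        g_b1 = d.exog_scale.T @ d_loglam
        g_b2 = d.exog_shape.T @ d_logk
        parts = ([np.array([g_theta])] if self._has_theta else []) + [g_b1, g_b2]
        return np.concatenate(parts)

    # -- fitting ----------------------------------------------------------
    def _starts(self, theta_starts) -> List[np.ndarray]:
        d = self.data
        p1, p2 = d.exog_scale.shape[1], d.exog_shape.shape[1]
        b1_0 = np.zeros(p1)
        b1_0[0] = np.log(np.mean(d.time))
        b2_0 = np.zeros(p2)
        base = np.concatenate([b1_0, b2_0])
        banks = []
        if self._has_theta:
            try:
                wb = WeibullRegression(self.data, None, None).fit(
                    theta_starts=())
                base_w = wb.params[0:]  # (beta_scale, beta_shape) of baseline
                for th in theta_starts:
                    banks.append(np.concatenate([[th], base_w]))
            except Exception:
                pass
            for th in theta_starts:
                banks.append(np.concatenate([[th], base]))
        else:
            banks.append(base)
        return banks

    def fit(self, theta_starts: Sequence[float] = (-2.0, -0.5, 0.5, 2.0),
            tol: float = 1e-12) -> "RegressionResults":
        def nll(p):
            v = -self.loglike(p)
            return v if np.isfinite(v) else 1e300

        def ngrad(p):
            theta = p[0] if self._has_theta else None
            if self._has_theta and p[0] == 0.0:
                p = p.copy()
                p[0] = 1e-300
            try:
                with np.errstate(over="ignore", invalid="ignore",
                                 divide="ignore"):
                    g = -self.score(p)
                return np.where(np.isfinite(g), g, 0.0)
            except (ValueError, FloatingPointError):
                return np.zeros_like(p)

        best, best_start, n_starts = None, None, 0
        for p0 in self._starts(theta_starts):
            n_starts += 1
            try:
                r = optimize.minimize(nll, p0, jac=ngrad, method="L-BFGS-B",
                                      options=dict(maxiter=1000, ftol=tol,
                                                   gtol=1e-9))
            except Exception:
                continue
            if np.isfinite(r.fun) and (best is None or r.fun < best.fun):
                best, best_start = r, {"start": p0.tolist(), "fun": float(r.fun)}
        if best is None or best.fun >= 1e299:
            raise RuntimeError("regression fit failed from every start")

        params = best.x.copy()
        ll = -float(best.fun)
        H = numdiff.approx_hess(params, nll)
        se, method = _se_from_hessian(H)
        return RegressionResults(
            model=self,
            param_names=self.param_names,
            params=params,
            se=se,
            loglik=ll,
            n=self.data.n,
            converged=bool(best.success),
            n_starts=n_starts,
            best_start=best_start,
            se_method=method,
        )

    # per-observation log f / log S at given params (used by residuals)
    def _log_parts(self, params):
        theta, b1, b2 = self._split(np.asarray(params, float))
        lam, k = _links(self.data, b1, b2)
        x = self.data.time
        return (tlw_logpdf(x, theta, k, lam), tlw_logsf(x, theta, k, lam),
                lam, k, theta)

    def _logcdf(self, params):
        from .tlw import tlw_cdf
        theta, b1, b2 = self._split(np.asarray(params, float))
        lam, k = _links(self.data, b1, b2)
        return np.log(np.clip(tlw_cdf(self.data.time, theta, k, lam),
                              1e-300, 1.0))


class WeibullRegression(TLWRegression):
    """Weibull baseline with the same two systematic components (no theta)."""

    family = "Weibull"
    _has_theta = False

    def loglike(self, params) -> float:
        _, b1, b2 = self._split(np.asarray(params, float))
        lam, k = _links(self.data, b1, b2)
        d = self.data
        x = d.time
        logz = np.clip(k * (np.log(x) - np.log(lam)), -745.0, 690.0)
        z = np.exp(logz)
        logf = np.log(k) - np.log(lam) + (k - 1.0) * (np.log(x) - np.log(lam)) - z
        ll = np.where(d.event == 1, logf, -z).sum()
        return float(ll) if np.isfinite(ll) else -np.inf

    def score(self, params) -> np.ndarray:
        _, b1, b2 = self._split(np.asarray(params, float))
        d = self.data
        lam, k = _links(d, b1, b2)
        x = d.time
        logz = np.clip(k * (np.log(x) - np.log(lam)), -745.0, 690.0)
        z = np.exp(logz)
        klx = k * (np.log(x) - np.log(lam))
        ev = d.event == 1
        d_logk = np.where(ev, 1.0 + klx * (1.0 - z), -klx * z)
        d_loglam = np.where(ev, -k * (1.0 - z), k * z)
        return np.concatenate([d.exog_scale.T @ d_loglam, d.exog_shape.T @ d_logk])

    def fit(self, theta_starts=(), tol: float = 1e-12) -> "RegressionResults":
        return super().fit(theta_starts=theta_starts, tol=tol)


@dataclass
class RegressionResults(FitResult):
    """Fit result for the censored regression; adds deviance and residuals."""

    model: object = None

    @property
    def global_deviance(self) -> float:
        """GD = -2 l, the deviance statistic reported next to AIC."""
        return -2.0 * self.loglik

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values against the standard normal."""
        zstat = self.params / self.se
        return 2.0 * stats.norm.sf(np.abs(zstat))

    def martingale_residuals(self) -> np.ndarray:
        """r_M = delta + log S(x | v) at the estimates; values in (-inf, 1]."""
        _, logS, *_ = self.model._log_parts(self.params)
        logS = np.asarray(logS, float)
        if np.any(~np.isfinite(logS)):
            warnings.warn("survival numerically zero for some observations; "
                          "martingale residuals clamped", RuntimeWarning)
            logS = np.maximum(logS, -700.0)
        return self.model.data.event + logS

    def deviance_residuals(self) -> np.ndarray:
        """Signed square-root transform of the martingale residuals."""
        rm = self.martingale_residuals()
        delta = self.model.data.event
        inner = delta - rm
        if np.any(inner <= 0):
            raise ValueError("invalid martingale residual (delta - r_M <= 0)")
        with np.errstate(invalid="ignore"):
            core = -2.0 * (rm + delta * np.log(inner))
        return np.sign(rm) * np.sqrt(np.maximum(core, 0.0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": f"{self.model.family} censored regression",
                "params": self.params_dict(),
                "se": dict(zip(self.param_names, map(float, self.se))),
                "pvalues": dict(zip(self.param_names, map(float, self.pvalues))),
                "loglik": self.loglik,
                "global_deviance": self.global_deviance,
                "aic": self.aic,
                "n": self.n,
                "n_events": self.model.data.n_events,
                "converged": self.converged,
            },
            indent=2,
        )

    def quantile_residuals(self) -> np.ndarray:
        """Phi^{-1}(F(x | v)); defined for fully observed samples only."""
        if self.model.data.n_events != self.model.data.n:
            raise ValueError("quantile residuals require an uncensored sample")
        logF = self.model._logcdf(self.params)
        F = np.clip(np.exp(logF), 1e-15, 1.0 - 1e-15)
        return stats.norm.ppf(F)

    def summary(self) -> str:
        base = [
            f"{self.model.family} censored regression "
            f"(n = {self.n}, events = {self.model.data.n_events})",
            f"  log-likelihood = {self.loglik:.4f}   GD = "
            f"{self.global_deviance:.4f}   AIC = {self.aic:.4f}",
            f"  {'param':>16} {'estimate':>12} {'std.err':>10} {'z':>8} "
            f"{'P>|z|':>8}",
        ]
        zs = self.params / self.se
        for name, est, se, z, p in zip(self.param_names, self.params, self.se,
                                       zs, self.pvalues):
            base.append(f"  {name:>16} {est:12.5f} {se:10.4f} {z:8.3f} {p:8.4f}")
        return "\n".join(base)


def kaplan_meier(time, event, group=None) -> Dict:
    """Product-limit survival estimate, optionally per group.

    Returns ``{group: (times, survival)}`` (single key ``None`` without
    groups); ``times`` are the distinct event times and ``survival`` the
    step-function values just after each.
    """
    time = np.asarray(time, float).ravel()
    event = np.asarray(event).ravel().astype(int)
    if group is None:
        group = np.zeros_like(event)
        keys = [None]
    else:
        group = np.asarray(group).ravel()
        keys = list(pd.unique(group))
    out = {}
    for key in keys:
        m = (group == (0 if key is None else key))
        t, e = time[m], event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t[e == 1])
        surv, s = [], 1.0
        for tj in uniq:
            d_j = int(((t == tj) & (e == 1)).sum())
            at_risk = int((t >= tj).sum())
            s *= 1.0 - d_j / at_risk
            surv.append(s)
        out[key] = (uniq, np.asarray(surv))
    return out
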