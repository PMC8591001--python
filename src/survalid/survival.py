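"""Survival engine: Kaplan–Meier, Cox PH with offset, right-censored Weibull AFT.

These are from-definition implementations because the central device of
score validation — an offset term whose coefficient is fixed at 1 in the
Cox partial likelihood — is not exposed by the usual Python survival
fitters. All fitters are deterministic given their inputs: no random
initialization, Newton-type iterations started from zero coefficients and
method-of-moments scale.

Model objects follow the construct-then-``fit()`` convention; ``fit()``
returns a results object carrying estimates, their covariance, likelihoods
and diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KaplanMeierCurve",
    "kaplan_meier",
    "km_median_ci",
    "CoxPH",
    "CoxPHResults",
    "fit_cox",
    "lr_test",
    "WeibullAFT",
    "WeibullAFTResults",
    "fit_weibull_aft",
    "ConvergenceError",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """An iterative fit failed; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclasses.dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimate with Greenwood variance.

    ``event_times`` are the distinct times with at least one event;
    ``survival`` is the right-continuous step value just after each.
    S(t) = 1 for t before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """S(t) by right-continuous step lookup; S(t)=1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return s if s.ndim else float(s)

    def confidence_band(self, alpha: float = 0.05):
        """Pointwise (1−alpha) band on the complementary log-log scale."""
        z = stats.norm.ppf(1 - alpha / 2)
        s = np.clip(self.survival, 1e-12, 1 - 1e-12)
        se_cll = np.sqrt(self.variance) / (s * np.abs(np.log(s)))
        lower = s ** np.exp(z * se_cll)
        upper = s ** np.exp(-z * se_cll)
        return lower, upper


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Kaplan–Meier estimate from right-censored data.

    Subjects censored at an event time are treated as censored just after
    the events at that time (they remain in the risk set for it).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one outcome")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n_total = t.size
    at_risk_all = n_total - first  # subjects with time >= each unique time
    d = np.zeros(uniq.size, dtype=int)
    np.add.at(d, np.searchsorted(uniq, t[e == 1]), 1)
    has_event = d > 0
    times = uniq[has_event]
    d = d[has_event]
    r = at_risk_all[has_event]
    frac = 1.0 - d / r
    surv = np.cumprod(frac)
    # Greenwood: var = S^2 * cumsum(d / (r (r - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(r > d, d / (r * (r - d)), np.nan))
    var = surv**2 * gw
    var = np.where(np.isnan(var), 0.0, var)
    return KaplanMeierCurve(times, surv, r, d, var, n=n_total)


def km_median_ci(curve: KaplanMeierCurve, alpha: float = 0.05):
    """Median survival time with a (1−alpha) CI from the cloglog band.

    Returns ``(median, (lower, upper))`` with ``None`` encoding "not
    reached" wherever the relevant curve never drops to 0.5.
    """

    def first_crossing(values: np.ndarray):
        hit = np.nonzero(values <= 0.5)[0]
        return float(curve.event_times[hit[0]]) if hit.size else None

    lower_band, upper_band = curve.confidence_band(alpha)
    median = first_crossing(curve.survival)
    return median, (first_crossing(lower_band), first_crossing(upper_band))


# ---------------------------------------------------------------------------
# Cox proportional hazards with offset (Efron ties)


class CoxPH:
    """Cox proportional-hazards model with optional unit-coefficient offset.

    Parameters
    ----------
    X : array (n, p) or None
        Free covariates. ``None`` or zero columns is allowed only when an
        offset is supplied (offset-only null model).
    time, event : arrays (n,)
        Right-censored outcome.
    offset : array (n,), optional
        Enters the linear predictor with coefficient fixed at 1 — the
        standard device for testing a published score against new data.
    names : sequence of str, optional
        Covariate names for reporting.

    Ties are handled with the Efron correction. The partial likelihood is
    maximized by Newton iterations with step-halving; the baseline
    cumulative hazard is the Breslow estimator anchored at covariate value
    0 and offset 0 (no mean-centering), keeping the baseline on the
    published score scale.
    """

    def __init__(self, X, time, event, offset=None, names=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = time.size
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n or event.size != n:
            raise ValueError("X, time, event must align")
        if event.sum() < 1:
            raise ValueError("need at least one event")
        if offset is None and X.shape[1] == 0:
            raise ValueError("zero covariates allowed only with an offset")
        self.names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
        if X.shape[1] > 0:
            const = np.all(X == X[0], axis=0)
            if const.any():
                raise ValueError(f"constant covariate column: {self.names[int(np.argmax(const))]!r}")
        self.offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        order = np.argsort(time, kind="stable")
        self._t = time[order]
        self._e = event[order]
        self._X = X[order]
        self._off = self.offset[order]
        self.n, self.p = X.shape
        # group structure: unique times, events per group
        self._uniq, self._first = np.unique(self._t, return_index=True)
        self._risk_start = self._first  # risk set for time u = rows [first:]

    # -- partial likelihood pieces ------------------------------------------
    def _pieces(self, beta):
        """Efron log partial likelihood, gradient and information at beta."""
        eta = self._X @ beta + self._off
        # shifting eta cancels exactly between the event terms and the
        # log-denominators, so ll is unchanged; it only guards overflow
        eta = eta - eta.max()
        w = np.exp(eta)
        p = self.p
        # suffix (reverse) cumulative sums over the time-sorted arrays
        S0 = np.cumsum(w[::-1])[::-1]
        if p:
            wx = w[:, None] * self._X
            S1 = np.cumsum(wx[::-1], axis=0)[::-1]
            wxx = wx[:, :, None] * self._X[:, None, :]
            S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for gi, start in enumerate(self._first):
            stop = self._first[gi + 1] if gi + 1 < self._first.size else self.n
            rows = slice(start, stop)
            ev = np.nonzero(self._e[rows])[0] + start
            d = ev.size
            if d == 0:
                continue
            s0 = S0[start]
            wD = w[ev]
            s0D = wD.sum()
            ll += eta[ev].sum()
            if p:
                s1 = S1[start]
                xD = self._X[ev]
                s1D = (wD[:, None] * xD).sum(axis=0)
                s2 = S2[start]
                s2D = (wD[:, None] * xD).T @ xD
                for l in range(d):
                    f = l / d
                    den = s0 - f * s0D
                    num1 = s1 - f * s1D
                    num2 = s2 - f * s2D
                    ll -= np.log(den)
                    grad_term = num1 / den
                    grad -= grad_term
                    info += num2 / den - np.outer(grad_term, grad_term)
                grad += xD.sum(axis=0)
            else:
                for l in range(d):
                    ll -= np.log(s0 - (l / d) * s0D)
        # undo the eta shift's effect on ll: each event contributed eta-max,
        # each log-denominator is log(sum exp(eta-max)) = log(sum exp eta) - max
        # so the shifts cancel exactly; ll is already correct.
        return ll, grad, info

    def loglike(self, beta=None) -> float:
        beta = np.zeros(self.p) if beta is None else np.asarray(beta, dtype=float)
        return self._pieces(beta)[0]

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "CoxPHResults":
        beta = np.zeros(self.p)
        ll, grad, info = self._pieces(beta)
        ll_null = ll  # beta = 0, offset retained
        grad_norm = float(np.linalg.norm(grad)) if self.p else 0.0
        it = 0
        if self.p:
            for it in range(1, max_iter + 1):
                try:
                    step = np.linalg.solve(info, grad)
                except np.linalg.LinAlgError:
                    bad = self._suspect_column(info)
                    raise ConvergenceError(
                        f"singular information matrix (suspect covariate {bad!r})",
                        {"iteration": it, "loglike": ll},
                    )
                # damped Newton: halve until the partial likelihood improves
                scale = 1.0
                for _ in range(30):
                    cand = beta + scale * step
                    ll_new, grad_new, info_new = self._pieces(cand)
                    if ll_new >= ll - 1e-12:
                        break
                    scale *= 0.5
                else:
                    raise ConvergenceError(
                        "step-halving failed to improve the partial likelihood",
                        {"iteration": it, "loglike": ll, "grad_norm": grad_norm},
                    )
                delta = np.max(np.abs(cand - beta))
                ll_change = abs(ll_new - ll)
                beta, ll, grad, info = cand, ll_new, grad_new, info_new
                grad_norm = float(np.linalg.norm(grad))
                if delta < 1e-9 or (ll_change < tol * (abs(ll) + 1.0) and grad_norm < 1e-6):
                    break
            else:
                raise ConvergenceError(
                    f"Cox fit did not converge in {max_iter} iterations",
                    {"loglike": ll, "grad_norm": grad_norm},
                )
            if grad_norm > 1e-4 * (1 + abs(ll)):
                raise ConvergenceError(
                    "Cox fit stalled with a large gradient",
                    {"loglike": ll, "grad_norm": grad_norm},
                )
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                bad = self._suspect_column(info)
                raise ConvergenceError(f"singular information at optimum (suspect {bad!r})")
            cov = (cov + cov.T) / 2
        else:
            cov = np.zeros((0, 0))
        baseline = self._breslow_baseline(beta)
        return CoxPHResults(
            model=self,
            params=beta,
            cov=cov,
            llf=float(ll),
            llnull=float(ll_null),
            niter=it,
            grad_norm=grad_norm,
            baseline_cumhaz=baseline,
        )

    def _suspect_column(self, info) -> str:
        if self.p == 0:
            return "<none>"
        diag = np.abs(np.diag(info))
        return self.names[int(np.argmin(diag))]

    def _breslow_baseline(self, beta) -> pd.DataFrame:
        """Breslow cumulative baseline hazard at the fitted coefficients."""
        eta = self._X @ beta + self._off
        w = np.exp(eta - eta.max())
        scale = np.exp(eta.max())
        S0 = np.cumsum(w[::-1])[::-1]
        times, increments = [], []
        for gi, start in enumerate(self._first):
            stop = self._first[gi + 1] if gi + 1 < self._first.size else self.n
            d = int(self._e[start:stop].sum())
            if d:
                times.append(self._uniq[gi])
                increments.append(d / (S0[start] * scale))
        cumhaz = np.cumsum(increments)
        return pd.DataFrame({"time": times, "cumhaz": cumhaz})


@dataclasses.dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, covariance, likelihoods, baseline."""

    model: CoxPH
    params: np.ndarray
    cov: np.ndarray
    llf: float
    llnull: float
    niter: int
    grad_norm: float
    baseline_cumhaz: pd.DataFrame

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)) if self.params.size else np.empty(0)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def hazard_ratios(self) -> pd.DataFrame:
        ci = np.exp(self.conf_int())
        return pd.DataFrame(
            {
                "HR": np.exp(self.params),
                "HR lower 95%": ci[:, 0],
                "HR upper 95%": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.model.names,
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "lower 95%": ci[:, 0],
                "upper 95%": ci[:, 1],
                "z": self.zvalues,
                "p": self.pvalues,
                "HR": np.exp(self.params),
            },
            index=self.model.names,
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.model.names),
            "coef": self.params.tolist(),
            "se": self.bse.tolist(),
            "llf": self.llf,
            "llnull": self.llnull,
            "niter": self.niter,
        }


def fit_cox(X, time, event, offset=None, names=None, **kwargs) -> CoxPHResults:
    """Convenience wrapper: build a :class:`CoxPH` and fit it."""
    return CoxPH(X, time, event, offset=offset, names=names).fit(**kwargs)


def lr_test(nested: CoxPHResults, full: CoxPHResults, df: int):
    """Likelihood-ratio test of a nested Cox model against a fuller one.

    Returns (statistic, p) with p from a chi-square on ``df`` degrees of
    freedom. A materially negative statistic signals mis-nesting.
    """
    statistic = 2.0 * (full.llf - nested.llf)
    if statistic < -1e-6:
        raise ValueError(f"negative LR statistic {statistic:.3g}: models are not nested on the same data")
    statistic = max(statistic, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


# ---------------------------------------------------------------------------
# Weibull accelerated failure time (log-linear, minimum extreme value errors)


class WeibullAFT:
    """Right-censored Weibull AFT model ln T = μ + γ·lp + σW.

    ``W`` follows the standard minimum (type 1) extreme-value distribution,
    so T is Weibull given the linear predictor. ``lp`` may be None for an
    intercept-only fit. σ is parameterized on the log scale; the covariance
    reported is that of (μ, γ, log σ) from the observed information.
    """

    def __init__(self, lp, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if (time <= 0).any():
            raise ValueError("all times must be positive for the log-time likelihood")
        if event.sum() < 2:
            raise ValueError("need at least 2 events")
        self.lp = None if lp is None else np.asarray(lp, dtype=float)
        if self.lp is not None and np.ptp(self.lp) == 0:
            raise ValueError("lp is constant; fit intercept-only (lp=None) instead")
        self.logt = np.log(time)
        self.event = event
        self.n = time.size
        self.k = 2 if self.lp is None else 3  # (mu, [gamma], log sigma)

    def _unpack(self, theta):
        if self.lp is None:
            mu, logsig = theta
            lin = mu
        else:
            mu, gamma, logsig = theta
            lin = mu + gamma * self.lp
        return lin, np.exp(logsig)

    def loglike(self, theta) -> float:
        lin, sigma = self._unpack(theta)
        z = (self.logt - lin) / sigma
        ez = np.exp(np.clip(z, -60.0, 60.0))
        ll = np.where(self.event == 1, -np.log(sigma) + z - ez, -ez)
        return float(ll.sum())

    def _neg_ll_grad(self, theta):
        lin, sigma = self._unpack(theta)
        z = (self.logt - lin) / sigma
        ez = np.exp(np.clip(z, -60.0, 60.0))
        d = self.event
        ll = np.sum(np.where(d == 1, -np.log(sigma) + z - ez, -ez))
        dl_dmu = np.sum(np.where(d == 1, (ez - 1), ez)) / sigma
        dl_dlogsig = np.sum(np.where(d == 1, -1 - z * (1 - ez), z * ez))
        if self.lp is None:
            grad = np.array([dl_dmu, dl_dlogsig])
        else:
            dl_dgamma = np.sum(np.where(d == 1, (ez - 1), ez) * self.lp) / sigma
            grad = np.array([dl_dmu, dl_dgamma, dl_dlogsig])
        return -ll, -grad

    def _start(self) -> np.ndarray:
        lt_ev = self.logt[self.event == 1]
        mu0 = float(lt_ev.mean())
        sig0 = max(float(lt_ev.std(ddof=1)) * np.sqrt(6.0) / np.pi, 0.05) if lt_ev.size > 1 else 1.0
        if self.lp is None:
            return np.array([mu0, np.log(sig0)])
        return np.array([mu0, 0.0, np.log(sig0)])

    def fit(self, tol: float = 1e-9, max_iter: int = 200) -> "WeibullAFTResults":
        res = optimize.minimize(
            self._neg_ll_grad,
            self._start(),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": max_iter},
        )
        theta = res.x
        # polish with Newton on the numerical Hessian for a tight optimum
        for _ in range(5):
            g = self._neg_ll_grad(theta)[1]
            H = _numerical_hessian(lambda th: self._neg_ll_grad(th)[0], theta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            cand = theta - step
            if self._neg_ll_grad(cand)[0] <= self._neg_ll_grad(theta)[0] + 1e-12:
                theta = cand
            if np.max(np.abs(step)) < 1e-12:
                break
        grad = self._neg_ll_grad(theta)[1]
        gnorm = float(np.linalg.norm(grad))
        if not np.all(np.isfinite(theta)) or gnorm > 1e-3 * (1 + abs(res.fun)):
            raise ConvergenceError("Weibull AFT fit did not converge", {"grad_norm": gnorm, "theta": theta.tolist()})
        sigma = float(np.exp(theta[-1]))
        if sigma < 1e-6:
            raise ConvergenceError("sigma collapsed toward zero", {"sigma": sigma})
        H = _numerical_hessian(lambda th: self._neg_ll_grad(th)[0], theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular observed information in Weibull AFT fit")
        cov = (cov + cov.T) / 2
        return WeibullAFTResults(
            model=self,
            mu=float(theta[0]),
            gamma=(None if self.lp is None else float(theta[1])),
            sigma=sigma,
            cov=cov,
            llf=float(-self._neg_ll_grad(theta)[0]),
            niter=int(res.nit),
        )


def _numerical_hessian(f, x, eps: float = 1e-5):
    """Central-difference Hessian of scalar f at x (small dimension only)."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclasses.dataclass
class WeibullAFTResults:
    """Fitted Weibull AFT: (μ, γ, σ) with covariance of (μ, γ, log σ)."""

    model: WeibullAFT
    mu: float
    gamma: float | None
    sigma: float
    cov: np.ndarray
    llf: float
    niter: int

    @property
    def params(self) -> np.ndarray:
        if self.gamma is None:
            return np.array([self.mu, np.log(self.sigma)])
        return np.array([self.mu, self.gamma, np.log(self.sigma)])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def summary(self) -> pd.DataFrame:
        names = ["mu", "log_sigma"] if self.gamma is None else ["mu", "gamma", "log_sigma"]
        ci = self.conf_int()
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "lower 95%": ci[:, 0], "upper 95%": ci[:, 1]},
            index=names,
        )


def fit_weibull_aft(lp, time, event, **kwargs) -> WeibullAFTResults:
    """Convenience wrapper: build a :class:`WeibullAFT` and fit it."""
    return WeibullAFT(lp, time, event).fit(**kwargs)
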