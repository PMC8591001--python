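"""Calibration assessment and Weibull recalibration of a survival risk score.

Calibration is judged in three ways:

* the calibration slope — the Cox coefficient of the LP fitted as the only
  covariate in the validation cohort (1 under correct relative risks);
* two calibration plots — per-risk-group Kaplan–Meier curves with mean
  predicted curves superimposed, and predicted-vs-observed survival at
  fixed horizons against the 45° line;
* the Weibull calibration model — the score is embedded in
  ln(T*) = μ + γ·LP + σW, where T* = H0(T) is the event time transformed
  by the derivation model's cumulative baseline hazard and W follows the
  standard minimum extreme-value distribution. Under perfect calibration
  H0(T)·exp(LP) is unit exponential, so (μ, γ, σ) = (0, −1, 1): μ
  measures the overall risk level, γ the impact of the LP, σ the shape of
  the baseline hazard. The fitted parameters then recalibrate the
  predicted curves via

      S_cal(t | LP) = exp(−exp((ln(−ln S0(t)) − μ − γ·LP) / σ)).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import RiskGroup, ScoreConfig
from .survival import WeibullAFT, fit_cox, kaplan_meier

__all__ = [
    "BaselineSurvival",
    "calibration_slope",
    "transform_time",
    "WeibullCalibration",
    "WeibullCalibrationResults",
    "fit_weibull_calibration",
    "recalibrated_survival",
    "grouped_calibration_table",
    "fixed_time_calibration_table",
    "plot_grouped_calibration",
    "plot_fixed_time_calibration",
]

#: Floor applied to transformed times T* = H0(t) before taking logs.
TSTAR_FLOOR = 1e-10

_Z = 1.959963984540054


class BaselineSurvival:
    """Baseline survival curve S0(t) from a knot table, with H0(t) = −ln S0(t).

    Interpolation between knots is linear in ln(−ln S0) versus ln t, which
    is exact when the baseline is Weibull. Below the first positive knot
    the first segment's slope is extended (H0(0) = 0); beyond the last
    knot evaluation raises unless ``extend`` is set, in which case the
    curve is held flat.
    """

    def __init__(self, table, extend: bool = False):
        tbl = np.asarray(table, dtype=float)
        if tbl.ndim != 2 or tbl.shape[1] != 2 or tbl.shape[0] < 2:
            raise ValueError("baseline table needs >= 2 (time, survival) rows")
        t, s = tbl[:, 0], tbl[:, 1]
        if t[0] != 0 or s[0] != 1:
            raise ValueError("baseline table must start at (0, 1)")
        if not (np.diff(t) > 0).all() or not ((s > 0) & (s <= 1)).all() or not (np.diff(s) <= 0).all():
            raise ValueError("baseline table must have increasing times and nonincreasing survival in (0, 1]")
        if (s[1:] >= 1).any():
            raise ValueError("survival must drop below 1 after time 0")
        self.knot_times = t
        self.knot_survival = s
        self.extend = extend
        self._log_t = np.log(t[1:])
        self._cll = np.log(-np.log(s[1:]))  # ln(−ln S0) at positive knots

    @classmethod
    def from_config(cls, config: ScoreConfig, extend: bool = False) -> "BaselineSurvival":
        return cls(config.baseline_survival, extend=extend)

    @property
    def horizon(self) -> float:
        return float(self.knot_times[-1])

    def cumhaz(self, t) -> np.ndarray:
        """H0(t) = −ln S0(t); H0(0) = 0."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if (t < 0).any():
            raise ValueError("negative time")
        over = t > self.knot_times[-1] * (1 + 1e-12)
        if over.any() and not self.extend:
            raise ValueError(
                f"time {t[over][0]:g} beyond baseline support {self.knot_times[-1]:g} "
                "(pass extend=True for a flat extension)"
            )
        tc = np.minimum(t, self.knot_times[-1])
        with np.errstate(divide="ignore"):
            logt = np.log(tc)
        cll = _interp_extrap(logt, self._log_t, self._cll)
        h = np.where(tc <= 0, 0.0, np.exp(cll))
        return float(h[0]) if scalar else h

    def survival(self, t):
        h = self.cumhaz(t)
        return np.exp(-h)

    def inverse_cumhaz(self, h) -> np.ndarray:
        """Smallest t with H0(t) = h; h beyond the table maps to +inf.

        Used to draw event times by inverse transform.
        """
        h = np.asarray(h, dtype=float)
        scalar = h.ndim == 0
        h = np.atleast_1d(h)
        if (h < 0).any():
            raise ValueError("negative cumulative hazard")
        h_max = float(self.cumhaz(self.knot_times[-1]))
        with np.errstate(divide="ignore"):
            cll = np.log(h)
        logt = _interp_extrap(cll, self._cll, self._log_t)
        t = np.where(h <= 0, 0.0, np.exp(logt))
        t = np.where(h > h_max, np.inf, t)
        return float(t[0]) if scalar else t


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation from the boundary segments."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        if lo.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
        if hi.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


# ---------------------------------------------------------------------------
# Calibration slope


def calibration_slope(lp, time, event):
    """Cox coefficient of the LP as the only covariate, with 95% CI.

    The first check of model validity: a slope near 1 means the relative
    risks transport to the validation cohort.
    """
    lp = np.asarray(lp, dtype=float)
    if np.ptp(lp) == 0:
        raise ValueError("lp is constant")
    res = fit_cox(lp[:, None], time, event, names=["lp"])
    ci = res.conf_int()[0]
    return float(res.params[0]), (float(ci[0]), float(ci[1])), res


# ---------------------------------------------------------------------------
# Weibull calibration model


def transform_time(time, baseline: BaselineSurvival):
    """Transform event times through the baseline cumulative hazard.

    T* = H0(T), floored at a small ε so ln T* stays finite; event
    indicators are unchanged by this monotone transform.
    """
    tstar = np.maximum(baseline.cumhaz(np.asarray(time, dtype=float)), TSTAR_FLOOR)
    return tstar


@dataclasses.dataclass
class WeibullCalibrationResults:
    """(μ, γ, σ) of the Weibull calibration model with tests against perfect
    calibration (μ = 0, γ = −1, σ = 1) and the conventional γ = 0 null."""

    mu: float
    gamma: float
    sigma: float
    cov: np.ndarray  # covariance of (mu, gamma, log sigma)
    llf: float
    n: int
    n_events: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def conf_int(self, alpha: float = 0.05) -> dict:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se
        return {
            "mu": (self.mu - z * se[0], self.mu + z * se[0]),
            "gamma": (self.gamma - z * se[1], self.gamma + z * se[1]),
            "sigma": (self.sigma * np.exp(-z * se[2]), self.sigma * np.exp(z * se[2])),
        }

    def _wald_p(self, value: float, null: float, se: float) -> float:
        return float(2 * stats.norm.sf(abs((value - null) / se)))

    @property
    def p_mu_zero(self) -> float:
        """Wald test of μ = 0: accuracy of the overall risk level."""
        return self._wald_p(self.mu, 0.0, self.se[0])

    @property
    def p_gamma_zero(self) -> float:
        """Wald test of γ = 0 (the conventional reported contrast)."""
        return self._wald_p(self.gamma, 0.0, self.se[1])

    @property
    def p_gamma_minus_one(self) -> float:
        """Wald test of γ = −1: the perfect-calibration value of the LP impact."""
        return self._wald_p(self.gamma, -1.0, self.se[1])

    @property
    def p_log_sigma_zero(self) -> float:
        """Wald test of σ = 1 (log σ = 0): correctly shaped baseline hazard."""
        return self._wald_p(np.log(self.sigma), 0.0, self.se[2])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": [self.mu, self.gamma, self.sigma],
                "lower 95%": [ci["mu"][0], ci["gamma"][0], ci["sigma"][0]],
                "upper 95%": [ci["mu"][1], ci["gamma"][1], ci["sigma"][1]],
                "perfect": [0.0, -1.0, 1.0],
                "p vs perfect": [self.p_mu_zero, self.p_gamma_minus_one, self.p_log_sigma_zero],
            },
            index=["mu", "gamma", "sigma"],
        )

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "mu": self.mu,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "se": self.se.tolist(),
            "ci": {k: list(v) for k, v in ci.items()},
            "p_mu_zero": self.p_mu_zero,
            "p_gamma_zero": self.p_gamma_zero,
            "p_gamma_minus_one": self.p_gamma_minus_one,
            "n": self.n,
            "n_events": self.n_events,
        }


class WeibullCalibration:
    """Model object: Weibull calibration of a score against a cohort.

    Composes the baseline-hazard time transform with a right-censored
    Weibull AFT fit of ln T* on the LP.
    """

    def __init__(self, lp, time, event, baseline: BaselineSurvival):
        self.lp = np.asarray(lp, dtype=float)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.baseline = baseline

    def fit(self, **kwargs) -> WeibullCalibrationResults:
        tstar = transform_time(self.time, self.baseline)
        aft = WeibullAFT(self.lp, tstar, self.event).fit(**kwargs)
        return WeibullCalibrationResults(
            mu=aft.mu,
            gamma=aft.gamma,
            sigma=aft.sigma,
            cov=aft.cov,
            llf=aft.llf,
            n=self.lp.size,
            n_events=int(self.event.sum()),
        )


def fit_weibull_calibration(lp, time, event, baseline: BaselineSurvival, **kwargs) -> WeibullCalibrationResults:
    """Convenience wrapper around :class:`WeibullCalibration`."""
    return WeibullCalibration(lp, time, event, baseline).fit(**kwargs)


def recalibrated_survival(t, lp, cal: WeibullCalibrationResults | tuple, baseline: BaselineSurvival):
    """Recalibrated survival probability S_cal(t | LP).

    Evaluates exp(−exp((ln(−ln S0(t)) − μ − γ·LP) / σ)). At
    (μ, γ, σ) = (0, 0, 1) this is S0(t); at (0, −1, 1) it is the original
    proportional-hazards prediction S0(t)^exp(LP). Vectorized over ``t``
    and ``lp`` jointly (broadcasting).
    """
    if isinstance(cal, tuple):
        mu, gamma, sigma = cal
    else:
        mu, gamma, sigma = cal.mu, cal.gamma, cal.sigma
    h0 = np.maximum(baseline.cumhaz(t), TSTAR_FLOOR)
    lp = np.asarray(lp, dtype=float)
    z = (np.log(h0) - mu - gamma * lp) / sigma
    return np.exp(-np.exp(z))


def predicted_survival(t, lp, baseline: BaselineSurvival):
    """Original-model prediction S0(t)^exp(LP) on the published score scale."""
    h0 = baseline.cumhaz(t)
    return np.exp(-np.outer(np.exp(np.asarray(lp, dtype=float)), np.atleast_1d(h0)))


# ---------------------------------------------------------------------------
# Calibration tables / plots


def grouped_calibration_table(
    time,
    event,
    lp,
    groups,
    baseline: BaselineSurvival,
    cal: WeibullCalibrationResults | None = None,
    grid=None,
) -> pd.DataFrame:
    """Per-risk-group observed KM versus mean predicted survival curves.

    Returns long-format rows (group, time, km, km_lower, km_upper,
    predicted_mean, recalibrated_mean). Empty groups are dropped.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    groups = np.asarray([g.value if isinstance(g, RiskGroup) else str(g) for g in groups])
    if grid is None:
        grid = np.linspace(0, min(time.max(), baseline.horizon), 49)
    rows = []
    for g in ("low", "intermediate", "high"):
        mask = groups == g
        if not mask.any():
            continue
        km = kaplan_meier(time[mask], event[mask])
        lo, hi = km.confidence_band()
        pred = predicted_survival(grid, lp[mask], baseline).mean(axis=0)
        recal = None
        if cal is not None:
            recal = np.array(
                [np.mean(recalibrated_survival(t, lp[mask], cal, baseline)) for t in grid]
            )
        for k, t in enumerate(grid):
            idx = np.searchsorted(km.event_times, t, side="right") - 1
            rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "km": float(km.survival_at(t)),
                    "km_lower": float(lo[idx]) if idx >= 0 else 1.0,
                    "km_upper": float(hi[idx]) if idx >= 0 else 1.0,
                    "predicted_mean": float(pred[k]),
                    "recalibrated_mean": float(recal[k]) if recal is not None else np.nan,
                    "n_group": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def fixed_time_calibration_table(
    time,
    event,
    lp,
    groups,
    baseline: BaselineSurvival,
    times=(12.0, 24.0),
    cal: WeibullCalibrationResults | None = None,
) -> pd.DataFrame:
    """Predicted vs KM-observed survival per group at fixed horizons.

    One row per (group, horizon): mean predicted probability, KM estimate
    with cloglog CI, and the recalibrated mean when ``cal`` is given.
    Groups empty at a horizon are omitted.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    groups = np.asarray([g.value if isinstance(g, RiskGroup) else str(g) for g in groups])
    rows = []
    for g in ("low", "intermediate", "high"):
        mask = groups == g
        if not mask.any():
            continue
        km = kaplan_meier(time[mask], event[mask])
        lo, hi = km.confidence_band()
        for t in times:
            idx = np.searchsorted(km.event_times, t, side="right") - 1
            pred = float(predicted_survival(t, lp[mask], baseline).mean())
            rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "predicted_mean": pred,
                    "recalibrated_mean": (
                        float(np.mean(recalibrated_survival(t, lp[mask], cal, baseline)))
                        if cal is not None
                        else np.nan
                    ),
                    "km": float(km.survival_at(t)),
                    "km_lower": float(lo[idx]) if idx >= 0 else 1.0,
                    "km_upper": float(hi[idx]) if idx >= 0 else 1.0,
                    "n_group": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def plot_grouped_calibration(table: pd.DataFrame, ax=None, title: str = ""):
    """Render the grouped calibration plot from its table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"low": "tab:green", "intermediate": "tab:orange", "high": "tab:red"}
    for g, sub in table.groupby("group", sort=False):
        c = colors.get(g, "tab:gray")
        ax.step(sub["time"], sub["km"], where="post", color=c, alpha=0.8, label=f"{g} (KM)")
        ax.fill_between(sub["time"], sub["km_lower"], sub["km_upper"], step="post", color=c, alpha=0.12)
        ax.plot(sub["time"], sub["predicted_mean"], color=c, linestyle="-", linewidth=2.2, alpha=0.5)
        if sub["recalibrated_mean"].notna().any():
            ax.plot(sub["time"], sub["recalibrated_mean"], color=c, linestyle="--", linewidth=1.6)
    ax.set_xlabel("Months since surgery")
    ax.set_ylabel("Recurrence-free survival")
    ax.set_ylim(0, 1.02)
    if len(table["group"].unique()) > 1:
        ax.legend(loc="lower left", fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_fixed_time_calibration(table: pd.DataFrame, ax=None, title: str = ""):
    """Predicted vs observed survival at fixed horizons against the 45° line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.8, 4.8))
    markers = {12.0: "o", 24.0: "s"}
    colors = {"low": "tab:green", "intermediate": "tab:orange", "high": "tab:red"}
    ax.plot([0, 1], [0, 1], color="black", linewidth=0.8)
    for _, row in table.iterrows():
        c = colors.get(row["group"], "tab:gray")
        m = markers.get(row["time"], "^")
        ax.errorbar(
            row["predicted_mean"],
            row["km"],
            yerr=[
                [max(row["km"] - row["km_lower"], 0.0)],
                [max(row["km_upper"] - row["km"], 0.0)],
            ],
            fmt=m,
            color=c,
            capsize=3,
            label=f"{row['group']} @ {row['time']:g}m",
        )
    ax.set_xlabel("Mean predicted survival")
    ax.set_ylabel("Observed (Kaplan–Meier) survival")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="upper left")
    if title:
        ax.set_title(title)
    return ax
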