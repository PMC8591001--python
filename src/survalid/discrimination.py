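"""Discrimination statistics for a risk score on right-censored outcomes.

Four measures, reported with bootstrap uncertainty:

* Harrell's C — fraction of usable pairs in which the higher-score patient
  fails first (ties in score count 1/2).
* Gönen–Heller K — concordance probability implied by the proportional-
  hazards model itself, a function of pairwise score differences only, and
  hence unaffected by censoring.
* Royston–Sauerbrei D and R²D — prognostic separation: the Cox coefficient
  of the normal-scores transform of the score ranks, and the explained-
  variation measure derived from it.
* tdAUC — inverse-probability-of-censoring-weighted cumulative/dynamic
  time-dependent ROC AUC, integrated over a follow-up window.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import stats

from .survival import fit_cox, kaplan_meier

__all__ = [
    "harrells_c",
    "gonen_heller_k",
    "royston_sauerbrei_r2d",
    "tdauc",
    "bootstrap_ci",
    "BootstrapResult",
    "DiscriminationReport",
]

_KAPPA = np.sqrt(8.0 / np.pi)  # Royston–Sauerbrei scaling constant


def harrells_c(lp, time, event) -> float:
    """Harrell's concordance index.

    A pair is usable when the smaller observed time is an event (and the
    times differ). It is concordant when the patient with the higher score
    has the shorter time; score ties count 1/2.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if lp.size < 2 or event.sum() < 1:
        raise ValueError("need >= 2 records and >= 1 event")
    conc = 0.0
    usable = 0
    # O(n^2) pair sweep; cohorts here are hundreds to a few thousand rows
    for i in np.nonzero(event == 1)[0]:
        later = time > time[i]
        usable += int(later.sum())
        conc += np.sum(lp[i] > lp[later]) + 0.5 * np.sum(lp[i] == lp[later])
    if usable == 0:
        raise ValueError("no usable pairs (all times tied or single event at the maximum)")
    return float(conc / usable)


def gonen_heller_k(lp) -> float:
    """Gönen–Heller concordance probability estimate.

    Averages, over all unordered pairs, the PH-model-implied probability
    that the higher-score patient fails first: 1 / (1 + exp(−|Δlp|)).
    Depends only on the fitted scores, so censoring never enters.
    """
    lp = np.asarray(lp, dtype=float)
    n = lp.size
    if n < 2:
        raise ValueError("need >= 2 records")
    diff = np.abs(lp[:, None] - lp[None, :])
    iu = np.triu_indices(n, k=1)
    return float(np.mean(1.0 / (1.0 + np.exp(-diff[iu]))))


def royston_sauerbrei_r2d(lp, time, event):
    """Royston–Sauerbrei prognostic separation D and R²D.

    Ranks the scores, maps ranks to expected standard-normal order
    statistics (Blom approximation), scales by κ = √(8/π), and takes D as
    the Cox coefficient of the constructed covariate. R²D = (D²/κ²) /
    (π²/6 + D²/κ²). Rank-based, hence invariant to increasing transforms
    of the score.
    """
    lp = np.asarray(lp, dtype=float)
    if np.unique(lp).size < 3:
        raise ValueError("need >= 3 distinct scores")
    n = lp.size
    ranks = stats.rankdata(lp, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    if np.ptp(z) == 0:
        return 0.0, 0.0
    res = fit_cox(z[:, None] / _KAPPA, time, event, names=["normal_scores"])
    d = float(res.params[0])
    d2k2 = (d / _KAPPA) ** 2
    return d, float(d2k2 / (np.pi**2 / 6.0 + d2k2))


def _censoring_km(time, event):
    """Kaplan–Meier of the censoring distribution (events and censorings swapped)."""
    return kaplan_meier(time, 1 - np.asarray(event, dtype=int))


def tdauc(lp, time, event, horizon: float, grid=None) -> float:
    """Integrated time-dependent cumulative/dynamic AUC over (0, horizon].

    At each time t, cases are subjects with an observed event at or before
    t, weighted by the inverse of the censoring-distribution Kaplan–Meier
    at their event time; controls are subjects still at risk beyond t. The
    AUC(t) values are integrated against the event-time distribution
    (−dS(t) weights from the Kaplan–Meier of the outcome), following the
    usual IPCW recipe.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    event_times = np.unique(time[(event == 1) & (time <= horizon)])
    if event_times.size == 0:
        raise ValueError("no events within the window")
    # evaluation grid: distinct event times, excluding any at which no
    # subject remains beyond t
    if grid is None:
        grid = event_times[event_times < time.max()]
        if grid.size == 0:
            grid = event_times
        if grid.size > 60:
            # cap the grid at 60 quantile-spaced event times; the -dS(t)
            # weighting below keeps the integral consistent
            grid = np.unique(np.quantile(grid, np.linspace(0, 1, 60), method="lower"))
    cens_km = _censoring_km(time, event)
    # G(t-): left-continuous censoring survival just before each subject's time
    g_at_event = np.array([_km_left(cens_km, t) for t in time])
    aucs = np.empty(grid.size)
    for k, t in enumerate(grid):
        is_case = (time <= t) & (event == 1)
        is_control = time > t
        if not is_case.any() or not is_control.any():
            aucs[k] = np.nan
            continue
        w = np.where(is_case, 1.0 / g_at_event, 0.0)
        lp_case = lp[is_case]
        w_case = w[is_case]
        lp_ctrl = lp[is_control]
        gt = (lp_case[:, None] > lp_ctrl[None, :]).astype(float)
        eq = (lp_case[:, None] == lp_ctrl[None, :]).astype(float)
        num = np.sum(w_case[:, None] * (gt + 0.5 * eq))
        den = w_case.sum() * is_control.sum()
        aucs[k] = num / den
    ok = ~np.isnan(aucs)
    if not ok.any():
        raise ValueError("AUC undefined at every grid time")
    grid, aucs = grid[ok], aucs[ok]
    if grid.size == 1:
        return float(aucs[0])
    surv_km = kaplan_meier(time, event)
    s = np.asarray(surv_km.survival_at(grid))
    s_prev = np.concatenate([[1.0], s[:-1]])
    weights = s_prev - s  # mass of the event-time distribution at each grid time
    if weights.sum() <= 0:
        return float(np.mean(aucs))
    return float(np.sum(aucs * weights) / weights.sum())


def _km_left(curve, t: float) -> float:
    """Left limit S(t−) of a Kaplan–Meier step function."""
    idx = np.searchsorted(curve.event_times, t, side="left") - 1
    return float(curve.survival[idx]) if idx >= 0 else 1.0


# ---------------------------------------------------------------------------
# Bootstrap


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    lower: float
    upper: float
    se: float
    n_replicates: int
    n_failed: int


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    n: int,
    B: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Normal-approximation bootstrap CI for a statistic of patient rows.

    ``statistic`` receives an integer index array (a resample of
    ``range(n)`` with replacement) and returns a scalar; the SE is the
    standard deviation over ``B`` replicates and the CI is estimate ±
    1.96·SE. Replicates on which the statistic raises are skipped and
    counted; more than ``max_failure_fraction`` failures is an error.
    Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(np.arange(n)))
    values = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(statistic(idx)))
        except Exception:
            failed += 1
    if failed > max_failure_fraction * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return BootstrapResult(
        estimate=estimate,
        lower=estimate - 1.959963984540054 * se,
        upper=estimate + 1.959963984540054 * se,
        se=se,
        n_replicates=len(values),
        n_failed=failed,
    )


@dataclasses.dataclass(frozen=True)
class DiscriminationReport:
    """The four discrimination statistics with bootstrap 95% CIs."""

    harrell_c: BootstrapResult
    gonen_heller_k: BootstrapResult
    royston_sauerbrei_r2d: BootstrapResult
    tdauc: BootstrapResult
    n_bootstrap: int

    def to_dict(self) -> dict:
        out = {}
        for key in ("harrell_c", "gonen_heller_k", "royston_sauerbrei_r2d", "tdauc"):
            r: BootstrapResult = getattr(self, key)
            out[key] = {"estimate": r.estimate, "lower": r.lower, "upper": r.upper, "se": r.se}
        out["n_bootstrap"] = self.n_bootstrap
        return out


def discrimination_report(lp, time, event, horizon: float, B: int = 200, seed: int = 0) -> DiscriminationReport:
    """All four statistics on one cohort with bootstrap CIs (B resamples)."""
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = lp.size

    def make(fn):
        return bootstrap_ci(fn, n, B=B, seed=seed)

    return DiscriminationReport(
        harrell_c=make(lambda idx: harrells_c(lp[idx], time[idx], event[idx])),
        gonen_heller_k=make(lambda idx: gonen_heller_k(lp[idx])),
        royston_sauerbrei_r2d=make(lambda idx: royston_sauerbrei_r2d(lp[idx], time[idx], event[idx])[1]),
        tdauc=make(lambda idx: tdauc(lp[idx], time[idx], event[idx], horizon)),
        n_bootstrap=B,
    )
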