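"""End-to-end external validation of a risk score on one cohort.

:class:`ScoreValidation` is the top-level model object: construct it from a
cohort and a score configuration, call :meth:`~ScoreValidation.fit`, and
receive a :class:`ValidationResults` carrying every stage in order —
complete-case accounting, risk-group table (counts, Kaplan–Meier medians,
hazard ratios against the low group), misspecification (calibration slope,
offset re-estimation, likelihood-ratio test), discrimination with
bootstrap CIs, and Weibull calibration with recalibrated curves — plus
``summary()`` and deterministic JSON / Markdown rendering.
"""

from __future__ import annotations

import dataclasses
import json
import sys

import numpy as np
import pandas as pd

from . import calibration as calib
from . import discrimination as disc
from .cohort import Cohort, ExclusionSummary, complete_case_filter, truncate_followup
from .scoring import RiskGroup, ScoreConfig, assign_risk_groups, compute_lp_cohort
from .survival import fit_cox, kaplan_meier, km_median_ci
from .updating import UpdateTrace, forward_selection, joint_misspecification_test, offset_extension_test

__all__ = ["ScoreValidation", "ValidationResults", "run_validation", "render_report"]

#: Default CLI-level seed: a memorable date-like constant.
DEFAULT_SEED = 20210707


def _fmt_median(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NR"
    return f"{value:.0f}"


@dataclasses.dataclass
class ValidationResults:
    """Everything one validation run produced, in report order."""

    cohort_label: str
    score_name: str
    n_input: int
    n_analyzed: int
    exclusions: ExclusionSummary
    horizon: float
    grouping_mode: str
    group_table: pd.DataFrame
    slope: float
    slope_ci: tuple[float, float]
    misspecification: "object"  # updating.MisspecificationTest
    discrimination: disc.DiscriminationReport
    weibull_calibration: calib.WeibullCalibrationResults
    grouped_calibration: pd.DataFrame
    fixed_time_calibration: pd.DataFrame
    hepatitis_tests: dict
    forward_trace: UpdateTrace | None
    lp: np.ndarray
    groups: list[RiskGroup]
    seed: int

    def summary(self) -> str:
        return render_report(self, fmt="markdown")

    def to_dict(self) -> dict:
        d = self.discrimination.to_dict()
        return {
            "cohort": self.cohort_label,
            "score": self.score_name,
            "n_input": self.n_input,
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.exclusions.n_excluded,
            "missing_per_field": self.exclusions.missing_per_field,
            "horizon_months": self.horizon,
            "grouping_mode": self.grouping_mode,
            "risk_groups": self.group_table.to_dict(orient="index"),
            "calibration_slope": {"estimate": self.slope, "ci": list(self.slope_ci)},
            "misspecification": self.misspecification.to_dict(),
            "discrimination": d,
            "weibull_calibration": self.weibull_calibration.to_dict(),
            "hepatitis_tests": {k: v.to_dict() for k, v in self.hepatitis_tests.items()},
            "forward_selection": self.forward_trace.to_dict() if self.forward_trace else None,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


class ScoreValidation:
    """Model object for validating one score on one cohort.

    Parameters
    ----------
    cohort
        Raw cohort (before complete-case filtering or truncation).
    score_config
        The score to validate (coefficients, cut-points, baseline table).
    horizon
        Administrative truncation of follow-up, months (default 24).
    grouping_mode
        ``'fixed'`` uses the published cut-points, ``'in_sample'`` the
        cohort's own 50th/85th LP percentiles.
    """

    def __init__(
        self,
        cohort: Cohort,
        score_config: ScoreConfig,
        horizon: float = 24.0,
        grouping_mode: str = "fixed",
    ):
        self.cohort = cohort
        self.config = score_config
        self.horizon = horizon
        self.grouping_mode = grouping_mode

    def fit(
        self,
        bootstrap: int = 200,
        seed: int = DEFAULT_SEED,
        hepatitis: tuple[str, ...] = ("hep_b", "hep_c"),
        forward_candidates: tuple[str, ...] = (),
        quiet: bool = True,
    ) -> ValidationResults:
        log = (lambda *a: None) if quiet else (lambda *a: print(*a, file=sys.stderr))

        # stage 1: complete cases, then truncate follow-up
        filtered, summary = complete_case_filter(self.cohort, self.config.covariates)
        log(f"[cohort] {summary.n_retained}/{summary.n_input} complete cases")
        if len(filtered) == 0:
            raise ValueError("no complete cases remain")
        cohort = truncate_followup(filtered, self.horizon)
        t, e = cohort.times, cohort.events
        log(f"[cohort] {int(e.sum())} events within {self.horizon:g} months")

        # stage 2: score and group
        lp = compute_lp_cohort(cohort, self.config)
        assignments = assign_risk_groups(lp, self.config, mode=self.grouping_mode)
        groups = [a.group for a in assignments]
        group_table = self._group_table(t, e, groups)
        log(f"[groups] counts: {group_table['n'].to_dict()}")

        # stage 3: misspecification
        slope, slope_ci, _ = calib.calibration_slope(lp, t, e)
        X, names = self._score_covariate_matrix(cohort)
        misspec = joint_misspecification_test(X, lp, t, e, names=names)
        log(f"[misspecification] slope={slope:.3f}, LR p={misspec.p:.3g}")

        # stage 4: discrimination with bootstrap
        report = disc.discrimination_report(lp, t, e, horizon=self.horizon, B=bootstrap, seed=seed)
        log(f"[discrimination] C={report.harrell_c.estimate:.3f}")

        # stage 5: calibration
        baseline = calib.BaselineSurvival.from_config(self.config)
        weibull = calib.WeibullCalibration(lp, t, e, baseline).fit()
        grouped = calib.grouped_calibration_table(t, e, lp, groups, baseline, cal=weibull)
        fixed_t = calib.fixed_time_calibration_table(
            t, e, lp, groups, baseline, times=(12.0, min(24.0, self.horizon)), cal=weibull
        )
        log(f"[calibration] mu={weibull.mu:.3f} gamma={weibull.gamma:.3f} sigma={weibull.sigma:.3f}")

        # stage 6: updating
        hep_tests = {}
        for name in hepatitis:
            vals = cohort.covariate(name)
            if np.isnan(vals).any():
                log(f"[updating] skipping {name}: missing values")
                continue
            hep_tests[name] = offset_extension_test(vals, lp, t, e, name=name)
        trace = None
        if forward_candidates:
            cands = {}
            for name in forward_candidates:
                vals = cohort.covariate(name)
                if not np.isnan(vals).any() and np.ptp(vals) > 0:
                    cands[name] = vals
            trace = forward_selection(cands, lp, t, e)

        return ValidationResults(
            cohort_label=cohort.label,
            score_name=self.config.name,
            n_input=summary.n_input,
            n_analyzed=len(cohort),
            exclusions=summary,
            horizon=self.horizon,
            grouping_mode=self.grouping_mode,
            group_table=group_table,
            slope=slope,
            slope_ci=slope_ci,
            misspecification=misspec,
            discrimination=report,
            weibull_calibration=weibull,
            grouped_calibration=grouped,
            fixed_time_calibration=fixed_t,
            hepatitis_tests=hep_tests,
            forward_trace=trace,
            lp=lp,
            groups=groups,
            seed=seed,
        )

    def _score_covariate_matrix(self, cohort: Cohort):
        """Design matrix of the score's own terms (transformed covariates)."""
        from .scoring import _covariate_values, _term_value  # shared transform logic

        raw = {f: cohort.covariate(f) for f in self.config.covariates}
        values = _covariate_values(raw, self.config)
        cols, names = [], []
        for term in self.config.terms:
            col = _term_value(term, values, self.config)
            if np.ptp(col) > 0:
                cols.append(col)
                names.append(f"{term.transform.value}({term.covariate})" if term.transform.value != "identity" else term.covariate)
        return np.column_stack(cols), names

    @staticmethod
    def _group_table(t, e, groups) -> pd.DataFrame:
        labels = np.asarray([g.value for g in groups])
        n_total = labels.size
        rows = {}
        present = [g for g in ("low", "intermediate", "high") if (labels == g).any()]
        # HRs vs low via a single Cox fit on group indicators
        hr = {g: (1.0, (1.0, 1.0)) if g == "low" else (np.nan, (np.nan, np.nan)) for g in present}
        if "low" in present and len(present) > 1:
            X = np.column_stack([(labels == g).astype(float) for g in present if g != "low"])
            try:
                res = fit_cox(X, t, e, names=[g for g in present if g != "low"])
                ci = np.exp(res.conf_int())
                for j, g in enumerate(n for n in present if n != "low"):
                    hr[g] = (float(np.exp(res.params[j])), (float(ci[j, 0]), float(ci[j, 1])))
            except Exception:
                pass
        for g in present:
            mask = labels == g
            km = kaplan_meier(t[mask], e[mask])
            median, (mlo, mhi) = km_median_ci(km)
            h, (hlo, hhi) = hr[g]
            rows[g] = {
                "n": int(mask.sum()),
                "pct": 100.0 * mask.sum() / n_total,
                "events": int(e[mask].sum()),
                "median_rfs": median,
                "median_lower": mlo,
                "median_upper": mhi,
                "hr": h,
                "hr_lower": hlo,
                "hr_upper": hhi,
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def run_validation(
    cohort: Cohort,
    score_config: ScoreConfig,
    horizon: float = 24.0,
    grouping_mode: str = "fixed",
    **fit_kwargs,
) -> ValidationResults:
    """One-call pipeline: build :class:`ScoreValidation` and fit it."""
    return ScoreValidation(cohort, score_config, horizon=horizon, grouping_mode=grouping_mode).fit(
        **fit_kwargs
    )


def render_report(results: ValidationResults, fmt: str = "markdown") -> str:
    """Deterministic serialization of a :class:`ValidationResults`.

    ``json`` round-trips via :meth:`ValidationResults.to_dict`; ``markdown``
    mirrors the usual layout of published validation tables (risk-group
    table, discrimination table, calibration parameters). Unreached
    Kaplan–Meier medians render as ``NR``.
    """
    if fmt == "json":
        return results.to_json()
    if fmt != "markdown":
        raise ValueError("fmt must be 'json' or 'markdown'")
    r = results
    lines = [
        f"# Validation of {r.score_name} on {r.cohort_label}",
        "",
        f"- analyzed: {r.n_analyzed} of {r.n_input} patients "
        f"({r.exclusions.n_excluded} excluded for missing covariates)",
        f"- follow-up truncated at {r.horizon:g} months; grouping: {r.grouping_mode}",
        f"- seed: {r.seed}",
        "",
        "## Risk groups",
        "",
        "| Group | n (%) | Events | Median RFS (95% CI) | HR (95% CI) |",
        "|---|---|---|---|---|",
    ]
    for g, row in r.group_table.iterrows():
        med = _fmt_median(row["median_rfs"])
        mlo = _fmt_median(row["median_lower"])
        mhi = _fmt_median(row["median_upper"])
        if g == "low":
            hr_txt = "1 (reference)"
        else:
            hr_txt = f"{row['hr']:.1f} ({row['hr_lower']:.1f}-{row['hr_upper']:.1f})"
        lines.append(
            f"| {g} | {int(row['n'])} ({row['pct']:.0f}) | {int(row['events'])} "
            f"| {med} ({mlo}-{mhi}) | {hr_txt} |"
        )
    lines += [
        "",
        "## Misspecification",
        "",
        f"- calibration slope: {r.slope:.2f} (95% CI {r.slope_ci[0]:.2f} to {r.slope_ci[1]:.2f})",
        f"- joint offset re-estimation: LR = {r.misspecification.lr_statistic:.2f} on "
        f"{r.misspecification.df} df, p = {r.misspecification.p:.3g}",
        "",
        "## Discrimination",
        "",
        "| Measure | Estimate (95% CI) |",
        "|---|---|",
    ]
    d = r.discrimination
    for label, br in (
        ("Harrell's C-index", d.harrell_c),
        ("Gonen & Heller's K", d.gonen_heller_k),
        ("Royston-Sauerbrei R2D", d.royston_sauerbrei_r2d),
        ("tdAUC", d.tdauc),
    ):
        lines.append(f"| {label} | {br.estimate:.2f} ({br.lower:.2f} to {br.upper:.2f}) |")
    lines += [
        f"\n(SEs from {d.n_bootstrap} bootstrap samples)",
        "",
        "## Weibull calibration",
        "",
        "| Parameter | Estimate (95% CI) | Perfect | p vs perfect |",
        "|---|---|---|---|",
    ]
    w = r.weibull_calibration
    ci = w.conf_int()
    for name, val, perfect, p in (
        ("mu", w.mu, 0.0, w.p_mu_zero),
        ("gamma", w.gamma, -1.0, w.p_gamma_minus_one),
        ("sigma", w.sigma, 1.0, w.p_log_sigma_zero),
    ):
        lo, hi = ci[name]
        lines.append(f"| {name} | {val:.2f} ({lo:.2f} to {hi:.2f}) | {perfect:g} | {p:.3g} |")
    lines.append(f"\n(gamma vs 0: p = {w.p_gamma_zero:.3g})")
    if r.hepatitis_tests:
        lines += ["", "## Hepatitis extension tests (LP as unit offset)", ""]
        for name, test in r.hepatitis_tests.items():
            lines.append(
                f"- {name}: {test.coefficient:.2f} (95% CI {test.ci[0]:.2f} to {test.ci[1]:.2f}), "
                f"p = {test.p:.3g}"
            )
    if r.forward_trace is not None:
        sel = ", ".join(r.forward_trace.selected) or "none"
        lines += ["", f"## Forward selection (lp_mode={r.forward_trace.lp_mode})", "", f"- selected: {sel}"]
    return "\n".join(lines) + "\n"
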