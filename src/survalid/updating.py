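"""Offset-constrained extension tests and forward selection for score revision.

All procedures keep the published score in the model as an offset (its
coefficient fixed at 1) and ask whether individual covariates carry
residual signal in the validation cohort. A fitted coefficient for a
covariate already inside the score is then the *difference* between its
derivation and validation log hazard ratios.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .survival import CoxPHResults, fit_cox, lr_test

__all__ = [
    "offset_extension_test",
    "joint_misspecification_test",
    "forward_selection",
    "ExtensionTest",
    "MisspecificationTest",
    "UpdateStep",
    "UpdateTrace",
]


@dataclasses.dataclass(frozen=True)
class ExtensionTest:
    covariate: str
    coefficient: float
    se: float
    ci: tuple[float, float]
    p: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def offset_extension_test(candidate, lp, time, event, name: str = "candidate") -> ExtensionTest:
    """Single-covariate extension test with the LP held as a unit offset.

    Fits a Cox model with ``lp`` as offset and ``candidate`` as the only
    free covariate; returns the Wald coefficient, CI and p-value.
    """
    candidate = np.asarray(candidate, dtype=float)
    if np.isnan(candidate).any():
        raise ValueError(f"candidate {name!r} has missing values")
    res = fit_cox(candidate[:, None], time, event, offset=lp, names=[name])
    ci = res.conf_int()[0]
    return ExtensionTest(
        covariate=name,
        coefficient=float(res.params[0]),
        se=float(res.bse[0]),
        ci=(float(ci[0]), float(ci[1])),
        p=float(res.pvalues[0]),
    )


@dataclasses.dataclass(frozen=True)
class MisspecificationTest:
    """Joint re-estimation of all score covariates alongside the unit-offset LP."""

    coefficients: pd.DataFrame  # per-covariate coef / se / CI / p
    lr_statistic: float
    df: int
    p: float
    fit: CoxPHResults

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(orient="index"),
            "lr_statistic": self.lr_statistic,
            "df": self.df,
            "p": self.p,
        }


def joint_misspecification_test(X, lp, time, event, names=None) -> MisspecificationTest:
    """All score covariates free alongside the unit-coefficient LP offset.

    The likelihood-ratio test against the offset-only null asks whether the
    re-estimated coefficient deviations are jointly nonzero — the overall
    misspecification test of the published score.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    full = fit_cox(X, time, event, offset=lp, names=names)
    null = fit_cox(None, time, event, offset=lp)
    statistic, p = lr_test(null, full, df=X.shape[1])
    ci = full.conf_int()
    table = pd.DataFrame(
        {
            "coef": full.params,
            "se": full.bse,
            "lower 95%": ci[:, 0],
            "upper 95%": ci[:, 1],
            "p": full.pvalues,
        },
        index=full.model.names,
    )
    return MisspecificationTest(table, float(statistic), X.shape[1], float(p), full)


@dataclasses.dataclass(frozen=True)
class UpdateStep:
    candidates: tuple[str, ...]
    table: pd.DataFrame  # per-candidate coef / se / p at this round
    selected: str | None
    loglik: float


@dataclasses.dataclass(frozen=True)
class UpdateTrace:
    steps: tuple[UpdateStep, ...]
    selected: tuple[str, ...]
    lp_mode: str
    entry_p: float

    def to_dict(self) -> dict:
        return {
            "lp_mode": self.lp_mode,
            "entry_p": self.entry_p,
            "selected": list(self.selected),
            "steps": [
                {
                    "candidates": list(s.candidates),
                    "selected": s.selected,
                    "loglik": s.loglik,
                    "table": s.table.to_dict(orient="index"),
                }
                for s in self.steps
            ],
        }


def forward_selection(
    candidates: dict[str, np.ndarray],
    lp,
    time,
    event,
    entry_p: float = 0.05,
    lp_mode: str = "offset",
) -> UpdateTrace:
    """p-value forward selection starting from the LP-only Cox model.

    Each round fits every remaining candidate on top of the current model
    and admits the one with the smallest Wald p, while that p is below
    ``entry_p``. ``lp_mode='offset'`` keeps the LP coefficient fixed at 1;
    ``'free'`` lets it be re-estimated. Ties in p are broken by candidate
    name so the trace is deterministic under column reordering.
    """
    if lp_mode not in ("offset", "free"):
        raise ValueError("lp_mode must be 'offset' or 'free'")
    lp = np.asarray(lp, dtype=float)
    remaining = sorted(candidates)
    chosen: list[str] = []
    steps: list[UpdateStep] = []

    def fit_with(extra: list[str]) -> CoxPHResults:
        cols = [candidates[c] for c in extra]
        if lp_mode == "offset":
            X = np.column_stack(cols) if cols else None
            return fit_cox(X, time, event, offset=lp, names=extra)
        X = np.column_stack([lp] + cols) if cols else lp[:, None]
        return fit_cox(X, time, event, names=["lp"] + extra)

    current = fit_with(chosen)
    while remaining:
        rows = []
        for name in remaining:
            try:
                res = fit_with(chosen + [name])
                j = res.model.names.index(name)
                rows.append((name, float(res.params[j]), float(res.bse[j]), float(res.pvalues[j]), res))
            except Exception:
                rows.append((name, np.nan, np.nan, np.nan, None))
        table = pd.DataFrame(
            [(n, c, s, p) for n, c, s, p, _ in rows], columns=["candidate", "coef", "se", "p"]
        ).set_index("candidate")
        valid = [(n, p, r) for n, _, _, p, r in rows if r is not None and np.isfinite(p)]
        if not valid:
            steps.append(UpdateStep(tuple(remaining), table, None, current.llf))
            break
        # smallest p, ties broken by name (list is name-sorted already)
        best_name, best_p, best_res = min(valid, key=lambda v: (v[1], v[0]))
        if best_p >= entry_p:
            steps.append(UpdateStep(tuple(remaining), table, None, current.llf))
            break
        steps.append(UpdateStep(tuple(remaining), table, best_name, best_res.llf))
        chosen.append(best_name)
        remaining.remove(best_name)
        current = best_res
    return UpdateTrace(tuple(steps), tuple(chosen), lp_mode, entry_p)
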