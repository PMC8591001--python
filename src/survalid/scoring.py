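"""ALBI grade, linear-predictor evaluation, and risk-group assignment.

A risk score here is a linear predictor LP = Σ βⱼ·fⱼ(xⱼ): a weighted sum of
(possibly transformed) covariates with published weights, evaluated per
patient, plus a rule that splits the LP scale into low / intermediate /
high risk groups — either at fixed published cut-points or at in-sample
percentiles (50th and 85th by convention, intending 50/35/15% groups).

The albumin–bilirubin (ALBI) liver-function grade enters such scores as an
indicator: ALBI score = 0.66·log10(bilirubin μmol/L) − 0.085·albumin g/L,
graded 1/2/3 at the cut-points −2.60 and −1.39.
"""

from __future__ import annotations

import dataclasses
import enum
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import Cohort, PatientRecord

__all__ = [
    "Transform",
    "ScoreTerm",
    "AlbiSpec",
    "GroupingRule",
    "ScoreConfig",
    "RiskGroup",
    "RiskAssignment",
    "compute_albi",
    "compute_lp",
    "compute_lp_cohort",
    "assign_risk_groups",
    "load_score_config",
    "builtin_config",
]

#: AFP values at or below zero are clamped to this floor before the log
#: transform (assay detection floor; ln(0) undefined).
AFP_FLOOR = 0.1


class Transform(str, enum.Enum):
    IDENTITY = "identity"
    LN = "ln"
    LOG10 = "log10"
    INDICATOR = "indicator"


_TRANSFORMS = {
    Transform.IDENTITY: lambda x: x,
    Transform.LN: np.log,
    Transform.LOG10: np.log10,
}


@dataclasses.dataclass(frozen=True)
class ScoreTerm:
    """One LP term: coefficient × transform(covariate).

    ``covariate`` names a PatientRecord field, or the derived quantities
    ``albi_grade_23`` (indicator of ALBI grade ≥ 2), ``multiple_tumors``
    (indicator of tumor_number > 1).
    """

    covariate: str
    transform: Transform
    coefficient: float
    threshold: float | None = None  # for generic indicator terms: 1 if x > threshold


@dataclasses.dataclass(frozen=True)
class AlbiSpec:
    bilirubin_coef: float = 0.66
    albumin_coef: float = -0.085
    cut_grade_1_2: float = -2.60
    cut_grade_2_3: float = -1.39

    def __post_init__(self) -> None:
        if not self.cut_grade_1_2 < self.cut_grade_2_3:
            raise ValueError("ALBI grade cut-points must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class GroupingRule:
    """Risk-group rule: fixed numeric cut-points and/or a percentile rule.

    ``fixed`` holds (low/intermediate boundary, intermediate/high boundary)
    on the LP scale; ``percentiles`` holds (p_low, p_high) in percent for
    in-sample grouping. A score may ship both.
    """

    fixed: tuple[float, float] | None = None
    percentiles: tuple[float, float] = (50.0, 85.0)

    def __post_init__(self) -> None:
        if self.fixed is not None and not self.fixed[0] < self.fixed[1]:
            raise ValueError("fixed cut-points must be strictly increasing")
        p_low, p_high = self.percentiles
        if not 0.0 < p_low < p_high < 100.0:
            raise ValueError("percentile rule requires 0 < p_low < p_high < 100")


@dataclasses.dataclass(frozen=True)
class ScoreConfig:
    """Full configuration of one LP-based risk score.

    ``baseline_survival`` is the derivation model's baseline survival table
    as (time months, survival probability) pairs: times strictly increasing
    from 0, probabilities nonincreasing in (0, 1], first entry (0, 1).
    """

    name: str
    terms: tuple[ScoreTerm, ...]
    albi: AlbiSpec
    grouping: GroupingRule
    baseline_survival: tuple[tuple[float, float], ...]
    source: str = ""

    def __post_init__(self) -> None:
        tbl = np.asarray(self.baseline_survival, dtype=float)
        if tbl.ndim != 2 or tbl.shape[1] != 2 or tbl.shape[0] < 2:
            raise ValueError("baseline_survival needs >= 2 (time, survival) rows")
        t, s = tbl[:, 0], tbl[:, 1]
        if t[0] != 0.0 or s[0] != 1.0:
            raise ValueError("baseline_survival must start at (0, 1)")
        if not (np.diff(t) > 0).all():
            raise ValueError("baseline_survival times must be strictly increasing")
        if not ((s > 0) & (s <= 1)).all() or not (np.diff(s) <= 0).all():
            raise ValueError("baseline_survival must be nonincreasing in (0, 1]")

    @property
    def covariates(self) -> tuple[str, ...]:
        """Raw PatientRecord fields the score reads (for complete-case filtering)."""
        fields: list[str] = []
        for term in self.terms:
            if term.covariate == "albi_grade_23":
                fields += ["albumin", "bilirubin"]
            elif term.covariate == "multiple_tumors":
                fields.append("tumor_number")
            else:
                fields.append(term.covariate)
        seen: list[str] = []
        for f in fields:
            if f not in seen:
                seen.append(f)
        return tuple(seen)


class RiskGroup(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclasses.dataclass(frozen=True)
class RiskAssignment:
    lp: float
    group: RiskGroup


def compute_albi(albumin: float, bilirubin: float, config: ScoreConfig | AlbiSpec | None = None):
    """ALBI score and grade from albumin (g/L) and bilirubin (μmol/L).

    Grade is 1 if score ≤ first cut-point, 2 if ≤ second, else 3
    (boundaries resolve downward). Vectorized over array inputs.
    """
    spec = config.albi if isinstance(config, ScoreConfig) else (config or AlbiSpec())
    albumin = np.asarray(albumin, dtype=float)
    bilirubin = np.asarray(bilirubin, dtype=float)
    if (albumin <= 0).any() or (bilirubin <= 0).any():
        raise ValueError("albumin and bilirubin must be strictly positive")
    score = spec.bilirubin_coef * np.log10(bilirubin) + spec.albumin_coef * albumin
    grade = np.where(score <= spec.cut_grade_1_2, 1, np.where(score <= spec.cut_grade_2_3, 2, 3))
    if score.ndim == 0:
        return float(score), int(grade)
    return score, grade


def _term_value(term: ScoreTerm, values: Mapping[str, np.ndarray], config: ScoreConfig):
    x = values[term.covariate]
    if term.transform is Transform.INDICATOR:
        thr = 0.5 if term.threshold is None else term.threshold
        return (x > thr).astype(float)
    if term.covariate == "afp" and term.transform in (Transform.LN, Transform.LOG10):
        x = np.maximum(x, AFP_FLOOR)
    return _TRANSFORMS[term.transform](x)


def _covariate_values(cohort_values: Mapping[str, np.ndarray], config: ScoreConfig) -> dict:
    values = dict(cohort_values)
    if any(t.covariate == "albi_grade_23" for t in config.terms):
        score, grade = compute_albi(values["albumin"], values["bilirubin"], config)
        values["albi_grade_23"] = (np.asarray(grade) >= 2).astype(float)
    if any(t.covariate == "multiple_tumors" for t in config.terms):
        values["multiple_tumors"] = (values["tumor_number"] > 1).astype(float)
    return values


def compute_lp(record: PatientRecord, config: ScoreConfig) -> float:
    """Evaluate the linear predictor for one patient record.

    Raises if any referenced covariate is missing (run the complete-case
    filter first).
    """
    for field in config.covariates:
        if record.is_missing(field):
            raise ValueError(f"covariate {field!r} missing for patient {record.id!r}")
    raw = {f: np.asarray(getattr(record, f), dtype=float) for f in config.covariates}
    values = _covariate_values(raw, config)
    lp = 0.0
    for term in config.terms:
        lp += term.coefficient * float(_term_value(term, values, config))
    return float(lp)


def compute_lp_cohort(cohort: Cohort, config: ScoreConfig) -> np.ndarray:
    """Vectorized LP over a cohort; covariates must be complete."""
    raw = {f: cohort.covariate(f) for f in config.covariates}
    for field, vals in raw.items():
        if np.isnan(vals).any():
            rid = cohort.frame["id"][np.isnan(vals)].iloc[0]
            raise ValueError(f"covariate {field!r} missing for patient {rid!r}")
    values = _covariate_values(raw, config)
    lp = np.zeros(len(cohort))
    for term in config.terms:
        lp = lp + term.coefficient * _term_value(term, values, config)
    return lp


def assign_risk_groups(
    lps: Sequence[float], config: ScoreConfig, mode: str = "fixed"
) -> list[RiskAssignment]:
    """Assign low / intermediate / high risk groups from LP values.

    ``fixed`` mode uses the config's numeric cut-points; ``in_sample``
    computes the configured percentiles (default 50th and 85th, linear
    interpolation between order statistics) of the supplied LPs. In both
    modes lp ≤ lower cut → low, lp ≤ upper cut → intermediate, else high.
    """
    lps = np.asarray(lps, dtype=float)
    if mode == "fixed":
        if config.grouping.fixed is None:
            raise ValueError(f"score {config.name!r} has no fixed cut-points configured")
        lo, hi = config.grouping.fixed
    elif mode == "in_sample":
        if len(np.unique(lps)) < 3:
            raise ValueError("in_sample grouping needs >= 3 distinct lp values")
        p_low, p_high = config.grouping.percentiles
        lo, hi = np.percentile(lps, [p_low, p_high], method="linear")
        if lo == hi:
            raise ValueError("degenerate lp distribution: percentile cut-points coincide")
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    groups = np.where(lps <= lo, "low", np.where(lps <= hi, "intermediate", "high"))
    return [RiskAssignment(float(lp), RiskGroup(str(g))) for lp, g in zip(lps, groups)]


# ---------------------------------------------------------------------------
# Config serialization


def _config_from_dict(data: dict) -> ScoreConfig:
    terms = tuple(
        ScoreTerm(
            covariate=t["covariate"],
            transform=Transform(t.get("transform", "identity")),
            coefficient=float(t["coefficient"]),
            threshold=t.get("threshold"),
        )
        for t in data["terms"]
    )
    albi = AlbiSpec(**data.get("albi", {}))
    grouping_data = data.get("grouping", {})
    fixed = grouping_data.get("fixed")
    grouping = GroupingRule(
        fixed=tuple(fixed) if fixed is not None else None,
        percentiles=tuple(grouping_data.get("percentiles", (50.0, 85.0))),
    )
    baseline = tuple((float(t), float(s)) for t, s in data["baseline_survival"])
    return ScoreConfig(
        name=data["name"],
        terms=terms,
        albi=albi,
        grouping=grouping,
        baseline_survival=baseline,
        source=data.get("source", ""),
    )


def load_score_config(path) -> ScoreConfig:
    """Load a score configuration from a YAML file."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def builtin_config(name: str) -> ScoreConfig:
    """Load a shipped score configuration: ``erasl_pre`` or ``erasl_post``."""
    ref = resources.files("survalid") / "configs" / f"{name}.yaml"
    return _config_from_dict(yaml.safe_load(ref.read_text()))
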