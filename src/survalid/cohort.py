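"""Patient cohort data model, I/O, complete-case filtering, and follow-up truncation.

A cohort is one row per patient with the covariates used by LP-based
recurrence risk scores (gender, albumin, bilirubin, AFP, tumor size and
number, optionally microvascular invasion and hepatitis B/C status) plus a
right-censored recurrence-free-survival outcome. Missing covariate values
are carried as ``NaN`` — a typed sentinel distinct from zero — and handled
by complete-case exclusion, mirroring how validation studies of these
scores treat missingness (no imputation).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SurvivalOutcome",
    "PatientRecord",
    "Cohort",
    "ExclusionSummary",
    "read_cohort",
    "complete_case_filter",
    "truncate_followup",
]

#: Canonical column names for cohort CSV files. ``read_cohort`` maps
#: arbitrary headers onto these via its ``schema`` argument.
CANONICAL_COLUMNS = (
    "id",
    "male",
    "albumin_g_l",
    "bilirubin_umol_l",
    "afp_ug_l",
    "tumor_size_cm",
    "tumor_number",
    "mvi",
    "hep_b",
    "hep_c",
    "rfs_months",
    "event",
)

#: Covariate fields a PatientRecord may carry (outcome fields excluded).
COVARIATE_FIELDS = (
    "male",
    "albumin",
    "bilirubin",
    "afp",
    "tumor_size",
    "tumor_number",
    "mvi",
    "hep_b",
    "hep_c",
)

_COLUMN_TO_FIELD = {
    "male": "male",
    "albumin_g_l": "albumin",
    "bilirubin_umol_l": "bilirubin",
    "afp_ug_l": "afp",
    "tumor_size_cm": "tumor_size",
    "tumor_number": "tumor_number",
    "mvi": "mvi",
    "hep_b": "hep_b",
    "hep_c": "hep_c",
}
_FIELD_TO_COLUMN = {v: k for k, v in _COLUMN_TO_FIELD.items()}

# Days per month used when a schema maps date columns upstream.
DAYS_PER_MONTH = 30.4375


class SchemaError(ValueError):
    """Required columns missing or unmappable in a cohort file."""


class CohortValidationError(ValueError):
    """A row violates an outcome or covariate invariant."""


@dataclasses.dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored event time in months since surgery.

    ``event`` is 1 if recurrence was observed at ``time`` and 0 if the
    patient was censored then (last radiologic examination, or death
    without recurrence).
    """

    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise CohortValidationError(f"time must be finite and >= 0, got {self.time!r}")
        if self.event not in (0, 1):
            raise CohortValidationError(f"event must be 0 or 1, got {self.event!r}")


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates and outcome. NaN marks a missing covariate."""

    id: str
    male: float
    albumin: float
    bilirubin: float
    afp: float
    tumor_size: float
    tumor_number: float
    mvi: float
    hep_b: float
    hep_c: float
    outcome: SurvivalOutcome

    def is_missing(self, field: str) -> bool:
        return bool(np.isnan(getattr(self, field)))


@dataclasses.dataclass(frozen=True)
class ExclusionSummary:
    """Complete-case filter accounting: per-field missing counts and totals."""

    n_input: int
    n_retained: int
    n_excluded: int
    missing_per_field: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class Cohort:
    """An ordered collection of patients, backed by a pandas DataFrame.

    The frame uses the canonical column names in :data:`CANONICAL_COLUMNS`.
    Patient ids must be unique.
    """

    def __init__(self, frame: pd.DataFrame, label: str = "cohort"):
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {missing}")
        ids = frame["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortValidationError(f"duplicate patient id {dup!r}")
        self._frame = frame.reset_index(drop=True)[list(CANONICAL_COLUMNS)].copy()
        self._frame["id"] = ids.to_numpy()
        self.label = label
        self._validate_outcomes()

    def _validate_outcomes(self) -> None:
        t = self._frame["rfs_months"].to_numpy(dtype=float)
        e = self._frame["event"].to_numpy(dtype=float)
        bad_t = ~np.isfinite(t) | (t < 0)
        if bad_t.any():
            rid = self._frame["id"][bad_t].iloc[0]
            raise CohortValidationError(f"negative or non-finite rfs_months for patient {rid!r}")
        bad_e = ~np.isin(e, (0.0, 1.0))
        if bad_e.any():
            rid = self._frame["id"][bad_e].iloc[0]
            raise CohortValidationError(f"event must be 0 or 1 for patient {rid!r}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterable[PatientRecord]:
        return (self.record(i) for i in range(len(self)))

    def record(self, i: int) -> PatientRecord:
        row = self._frame.iloc[i]
        return PatientRecord(
            id=str(row["id"]),
            male=float(row["male"]),
            albumin=float(row["albumin_g_l"]),
            bilirubin=float(row["bilirubin_umol_l"]),
            afp=float(row["afp_ug_l"]),
            tumor_size=float(row["tumor_size_cm"]),
            tumor_number=float(row["tumor_number"]),
            mvi=float(row["mvi"]),
            hep_b=float(row["hep_b"]),
            hep_c=float(row["hep_c"]),
            outcome=SurvivalOutcome(float(row["rfs_months"]), int(row["event"])),
        )

    # -- views --------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the underlying canonical-column frame."""
        return self._frame.copy()

    @property
    def times(self) -> np.ndarray:
        return self._frame["rfs_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self._frame["event"].to_numpy(dtype=int)

    def covariate(self, field: str) -> np.ndarray:
        return self._frame[_FIELD_TO_COLUMN[field]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    def with_frame(self, frame: pd.DataFrame, label: str | None = None) -> "Cohort":
        return Cohort(frame, label if label is not None else self.label)


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    label: str | None = None,
    delimiter: str = ",",
) -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Mapping from canonical column name to the column name in the file.
        Columns already canonically named need no entry. Optional covariates
        (mvi, hep_b, hep_c) absent from the file become all-missing.
    label
        Cohort label; defaults to the file stem.
    delimiter
        Field delimiter, comma by default.

    Unparseable or blank cells become NaN missing markers; row order is
    preserved. Negative times or non-binary event codes raise
    :class:`CohortValidationError` naming the offending patient.
    """
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = schema.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    raw = raw.rename(columns=rename)

    required = ["id", "rfs_months", "event"]
    missing_req = [c for c in required if c not in raw.columns]
    if missing_req:
        raise SchemaError(f"required columns missing from {path}: {missing_req}")

    frame = pd.DataFrame()
    frame["id"] = raw["id"].astype(str)
    for col in CANONICAL_COLUMNS:
        if col == "id":
            continue
        if col in raw.columns:
            frame[col] = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        elif col in ("mvi", "hep_b", "hep_c"):
            frame[col] = np.nan
        else:
            raise SchemaError(f"required column {col!r} missing from {path}")

    if frame["rfs_months"].isna().any() or frame["event"].isna().any():
        bad = frame["id"][frame["rfs_months"].isna() | frame["event"].isna()].iloc[0]
        raise CohortValidationError(f"unparseable outcome for patient {bad!r}")

    if label is None:
        import pathlib

        label = pathlib.Path(str(path)).stem
    return Cohort(frame, label=str(label))


def complete_case_filter(
    cohort: Cohort, required: Sequence[str]
) -> tuple[Cohort, ExclusionSummary]:
    """Drop records with any missing value among ``required`` covariates.

    Returns the filtered cohort and an :class:`ExclusionSummary` with
    per-field missing counts (a record missing two fields is counted under
    both, but excluded once). An empty result is allowed; callers decide
    whether that is fatal.
    """
    unknown = [f for f in required if f not in COVARIATE_FIELDS]
    if unknown:
        raise ValueError(f"unknown covariate fields: {unknown}")
    frame = cohort.frame
    cols = [_FIELD_TO_COLUMN[f] for f in required]
    miss = frame[cols].isna()
    keep = ~miss.any(axis=1)
    summary = ExclusionSummary(
        n_input=len(frame),
        n_retained=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        missing_per_field={f: int(miss[_FIELD_TO_COLUMN[f]].sum()) for f in required},
    )
    return cohort.with_frame(frame[keep]), summary


def truncate_followup(cohort: Cohort, horizon: float = 24.0) -> Cohort:
    """Administratively censor follow-up at ``horizon`` months.

    Records with time beyond the horizon become censored exactly at the
    horizon; all others are unchanged. Idempotent.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    frame = cohort.frame
    over = frame["rfs_months"] > horizon
    frame.loc[over, "rfs_months"] = horizon
    frame.loc[over, "event"] = 0
    return cohort.with_frame(frame)
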