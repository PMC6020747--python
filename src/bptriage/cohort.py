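"""Cohort domain types, CSV reading/writing, and eligibility filtering.

A cohort is a list of patients, each carrying a clinic visit (>= 3 seated BP
readings for eligible patients), an ABPM session (raw readings and/or
precomputed period means), and the covariates the out-of-office prediction
model consumes (age, sex, BMI, hypertension and treatment history,
cardiovascular disease).

Two CSV dialects are accepted, selected by a :class:`SchemaConfig`:

``wide``
    One row per patient.  Clinic readings live in numbered columns
    (``sbp1..sbpK`` / ``dbp1..dbpK``); ABPM appears as period means
    (``abpm_day_sbp`` ...).

``long``
    One row per reading, repeated covariates, with a ``reading_kind`` column
    distinguishing clinic readings, raw ABPM readings and precomputed ABPM
    period means.
"""
from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
import yaml

from .exceptions import CohortSchemaError
from .reference import MeanBP, Period

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Smoking",
    "Setting",
    "ExclusionReason",
    "ClinicReading",
    "ClinicVisit",
    "AbpmReading",
    "AbpmSession",
    "PatientRecord",
    "Cohort",
    "ExclusionLog",
    "SchemaConfig",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "DEFAULT_REQUIRED_COVARIATES",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Smoking(str, enum.Enum):
    CURRENT = "current"
    FORMER = "former"
    NEVER = "never"
    UNKNOWN = "unknown"


class Setting(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


class ExclusionReason(str, enum.Enum):
    MISSING_BP = "missing_bp"
    UNDER_18 = "under_18"
    MISSING_CLINICAL_INFO = "missing_clinical_info"
    ABPM_NOT_WORN = "abpm_not_worn"


@dataclass(frozen=True, slots=True)
class ClinicReading:
    """One seated clinic BP reading; ``order_index`` is 1-based position
    within the visit (the first reading is typically the most elevated)."""

    systolic: float
    diastolic: float
    order_index: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.systolic) and math.isfinite(self.diastolic)):
            raise ValueError("clinic reading must be finite")
        if not self.systolic > self.diastolic > 0:
            raise ValueError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic}"
            )
        if self.order_index < 1:
            raise ValueError("order_index is 1-based")


@dataclass(frozen=True, slots=True)
class ClinicVisit:
    """An ordered series of clinic readings from a single visit."""

    readings: tuple[ClinicReading, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))

    def __len__(self) -> int:
        return len(self.readings)


@dataclass(frozen=True, slots=True)
class AbpmReading:
    """One ambulatory reading flagged with its monitoring period."""

    systolic: float
    diastolic: float
    period: Period = Period.DAY

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > 0:
            raise ValueError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic}"
            )
        object.__setattr__(self, "period", Period(self.period))
        if self.period is Period.H24:
            raise ValueError("raw readings are flagged day or night, not h24")


@dataclass(frozen=True, slots=True)
class AbpmSession:
    """Raw ABPM readings and/or precomputed period means.

    Precomputed means take precedence over raw readings when both are
    present (some sites only report period summaries).
    """

    readings: tuple[AbpmReading, ...] = ()
    daytime_mean: MeanBP | None = None
    night_mean: MeanBP | None = None
    h24_mean: MeanBP | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))

    def summary_for(self, period: Period) -> MeanBP | None:
        return {
            Period.DAY: self.daytime_mean,
            Period.NIGHT: self.night_mean,
            Period.H24: self.h24_mean,
        }[Period(period)]

    def has_period(self, period: Period) -> bool:
        period = Period(period)
        if self.summary_for(period) is not None:
            return True
        if period is Period.H24:
            return len(self.readings) > 0
        return any(Period(r.period) is period for r in self.readings)


@dataclass(slots=True)
class PatientRecord:
    """Covariates, clinic visit, and ABPM session for one individual."""

    id: str
    visit: ClinicVisit
    abpm: AbpmSession
    age: float | None = None
    sex: Sex | None = None
    bmi: float | None = None
    smoking: Smoking = Smoking.UNKNOWN
    diabetes: bool | None = None
    ckd: bool | None = None
    af: bool | None = None
    cvd_history: bool | None = None
    hypertension_diagnosis: bool | None = None
    n_antihypertensives: int | None = None
    setting: Setting | None = None

    def __post_init__(self) -> None:
        if self.bmi is not None and not self.bmi > 0:
            raise ValueError("bmi must be positive when present")
        if self.n_antihypertensives is not None and self.n_antihypertensives < 0:
            raise ValueError("n_antihypertensives must be >= 0")

    @property
    def treated(self) -> bool | None:
        """On antihypertensive treatment (>= 1 drug)."""
        if self.n_antihypertensives is None:
            return None
        return self.n_antihypertensives >= 1


@dataclass(slots=True)
class Cohort:
    """A list of patient records with unique ids."""

    patients: list[PatientRecord]
    provenance: str = ""
    parse_errors: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.id: p for p in self.patients}


@dataclass(slots=True)
class ExclusionLog:
    """One (patient id, primary reason) entry per excluded patient."""

    entries: list[tuple[str, ExclusionReason]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[ExclusionReason, int]:
        out = {r: 0 for r in ExclusionReason}
        for _, reason in self.entries:
            out[reason] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, r.value) for i, r in self.entries], columns=["id", "reason"]
        )


# ---------------------------------------------------------------------------
# CSV schema


@dataclass(slots=True)
class SchemaConfig:
    """Column mapping for cohort CSV files.

    ``columns`` maps canonical names (``id``, ``age``, ``sex``, ``bmi``,
    ``smoking``, ``diabetes``, ``ckd``, ``af``, ``cvd_history``,
    ``hypertension_diagnosis``, ``n_antihypertensives``, ``setting``, the
    ABPM summary columns, and in long layout ``reading_kind``,
    ``order_index``, ``systolic``, ``diastolic``) to the file's column
    names; unmapped names default to themselves.
    """

    layout: str = "wide"  # "wide" | "long"
    columns: dict[str, str] = field(default_factory=dict)
    clinic_sbp_prefix: str = "sbp"
    clinic_dbp_prefix: str = "dbp"

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise CohortSchemaError(f"unknown layout {self.layout!r}")

    def col(self, name: str) -> str:
        return self.columns.get(name, name)

    @classmethod
    def from_file(cls, path: str | Path) -> "SchemaConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))


_COVARIATES = (
    "age", "sex", "bmi", "smoking", "diabetes", "ckd", "af",
    "cvd_history", "hypertension_diagnosis", "n_antihypertensives", "setting",
)
_ABPM_SUMMARY_COLS = {
    Period.DAY: ("abpm_day_sbp", "abpm_day_dbp"),
    Period.NIGHT: ("abpm_night_sbp", "abpm_night_dbp"),
    Period.H24: ("abpm_24h_sbp", "abpm_24h_dbp"),
}

#: Covariates the default out-of-office prediction model requires.
DEFAULT_REQUIRED_COVARIATES = (
    "age", "sex", "bmi", "hypertension_diagnosis",
    "n_antihypertensives", "cvd_history",
)

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or (
        isinstance(v, str) and v.strip() == ""
    )


def _parse_float(v) -> float | None:
    if _is_missing(v):
        return None
    return float(v)


def _parse_int(v) -> int | None:
    f = _parse_float(v)
    return None if f is None else int(round(f))


def _parse_bool(v) -> bool | None:
    if _is_missing(v):
        return None
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    try:
        return bool(int(float(s)))
    except ValueError:
        return None


def _parse_enum(enum_cls, v, fallback=None):
    if _is_missing(v):
        return fallback
    s = str(v).strip().lower()
    try:
        return enum_cls(s)
    except ValueError:
        return fallback


def _parse_covariates(row: pd.Series, schema: SchemaConfig) -> dict:
    def get(name):
        c = schema.col(name)
        return row[c] if c in row.index else None

    return dict(
        age=_parse_float(get("age")),
        sex=_parse_enum(Sex, get("sex")),
        bmi=_parse_float(get("bmi")),
        smoking=_parse_enum(Smoking, get("smoking"), Smoking.UNKNOWN),
        diabetes=_parse_bool(get("diabetes")),
        ckd=_parse_bool(get("ckd")),
        af=_parse_bool(get("af")),
        cvd_history=_parse_bool(get("cvd_history")),
        hypertension_diagnosis=_parse_bool(get("hypertension_diagnosis")),
        n_antihypertensives=_parse_int(get("n_antihypertensives")),
        setting=_parse_enum(Setting, get("setting")),
    )


def _summary_or_none(s, d) -> MeanBP | None:
    fs, fd = _parse_float(s), _parse_float(d)
    if fs is None or fd is None:
        return None
    return MeanBP(fs, fd)


def _read_wide(df: pd.DataFrame, schema: SchemaConfig,
               errors: list[str]) -> list[PatientRecord]:
    id_col = schema.col("id")
    if id_col not in df.columns:
        raise CohortSchemaError(f"missing mandatory column {id_col!r}")
    sbp_cols, dbp_cols = [], []
    k = 1
    while f"{schema.clinic_sbp_prefix}{k}" in df.columns:
        sbp_cols.append(f"{schema.clinic_sbp_prefix}{k}")
        dbp = f"{schema.clinic_dbp_prefix}{k}"
        if dbp not in df.columns:
            raise CohortSchemaError(f"missing mandatory column {dbp!r}")
        dbp_cols.append(dbp)
        k += 1
    if not sbp_cols:
        raise CohortSchemaError(
            f"missing mandatory column {schema.clinic_sbp_prefix + '1'!r} "
            "(no clinic BP columns found)"
        )

    patients = []
    for _, row in df.iterrows():
        pid = str(row[id_col])
        try:
            readings = []
            for j, (sc, dc) in enumerate(zip(sbp_cols, dbp_cols), start=1):
                s, d = _parse_float(row[sc]), _parse_float(row[dc])
                if s is None and d is None:
                    continue  # ragged visits: trailing blanks allowed
                if s is None or d is None:
                    raise ValueError(f"half-missing clinic reading {j}")
                readings.append(ClinicReading(s, d, order_index=j))
            session = AbpmSession(
                daytime_mean=_summary_or_none(
                    row.get(schema.col("abpm_day_sbp")),
                    row.get(schema.col("abpm_day_dbp"))),
                night_mean=_summary_or_none(
                    row.get(schema.col("abpm_night_sbp")),
                    row.get(schema.col("abpm_night_dbp"))),
                h24_mean=_summary_or_none(
                    row.get(schema.col("abpm_24h_sbp")),
                    row.get(schema.col("abpm_24h_dbp"))),
            )
            patients.append(PatientRecord(
                id=pid, visit=ClinicVisit(tuple(readings)), abpm=session,
                **_parse_covariates(row, schema)))
        except (ValueError, TypeError) as exc:
            msg = f"row for patient {pid!r} skipped: {exc}"
            errors.append(msg)
            logger.warning("%s", msg)
    return patients


def _read_long(df: pd.DataFrame, schema: SchemaConfig,
               errors: list[str]) -> list[PatientRecord]:
    for name in ("id", "reading_kind", "systolic", "diastolic"):
        if schema.col(name) not in df.columns:
            raise CohortSchemaError(f"missing mandatory column {schema.col(name)!r}")
    id_col, kind_col = schema.col("id"), schema.col("reading_kind")
    s_col, d_col = schema.col("systolic"), schema.col("diastolic")
    order_col = schema.col("order_index")

    patients = []
    for pid, grp in df.groupby(id_col, sort=False):
        pid = str(pid)
        clinic: list[ClinicReading] = []
        abpm: list[AbpmReading] = []
        summaries: dict[str, MeanBP] = {}
        cov_row = grp.iloc[0]
        bad = False
        for _, row in grp.iterrows():
            kind = str(row[kind_col]).strip().lower()
            try:
                s, d = _parse_float(row[s_col]), _parse_float(row[d_col])
                if s is None or d is None:
                    raise ValueError("missing pressure value")
                if kind == "clinic":
                    idx = _parse_int(row.get(order_col)) or (len(clinic) + 1)
                    clinic.append(ClinicReading(s, d, order_index=idx))
                elif kind in ("abpm_day", "abpm_night"):
                    abpm.append(AbpmReading(s, d, period=Period(kind.removeprefix("abpm_"))))
                elif kind in ("abpm_day_mean", "abpm_night_mean", "abpm_24h_mean"):
                    summaries[kind] = MeanBP(s, d)
                else:
                    raise ValueError(f"unknown reading_kind {kind!r}")
            except (ValueError, TypeError) as exc:
                msg = f"reading row for patient {pid!r} skipped: {exc}"
                errors.append(msg)
                logger.warning("%s", msg)
                bad = True
        if bad and not clinic and not abpm and not summaries:
            continue
        clinic.sort(key=lambda r: r.order_index)
        session = AbpmSession(
            readings=tuple(abpm),
            daytime_mean=summaries.get("abpm_day_mean"),
            night_mean=summaries.get("abpm_night_mean"),
            h24_mean=summaries.get("abpm_24h_mean"),
        )
        patients.append(PatientRecord(
            id=pid, visit=ClinicVisit(tuple(clinic)), abpm=session,
            **_parse_covariates(cov_row, schema)))
    return patients


def read_cohort(path: str | Path, schema: SchemaConfig | None = None) -> Cohort:
    """Read a cohort CSV.

    Rows with unparseable blood pressure values are skipped and recorded in
    ``Cohort.parse_errors`` (and the module logger); a missing mandatory
    column raises :class:`CohortSchemaError` naming the column.

    Without an explicit schema the layout is sniffed from the header: a
    ``reading_kind`` column marks the long dialect.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if schema is None:
        layout = "long" if "reading_kind" in df.columns else "wide"
        schema = SchemaConfig(layout=layout)
    errors: list[str] = []
    if schema.layout == "wide":
        patients = _read_wide(df, schema, errors)
    else:
        patients = _read_long(df, schema, errors)
    return Cohort(patients, provenance=str(path), parse_errors=errors)


def _cov_cells(p: PatientRecord) -> dict[str, object]:
    def enc(v):
        if v is None:
            return ""
        if isinstance(v, enum.Enum):
            return v.value
        if isinstance(v, bool):
            return int(v)
        return v

    return {name: enc(getattr(p, name)) for name in _COVARIATES}


def write_cohort(cohort: Cohort, path: str | Path, layout: str = "wide") -> None:
    """Write a cohort CSV in the wide or long dialect.

    The wide dialect stores ABPM period means only; cohorts carrying raw
    ABPM readings should be written long to remain lossless.
    """
    path = Path(path)
    rows = []
    if layout == "wide":
        kmax = max((len(p.visit) for p in cohort), default=0)
        for p in cohort:
            row: dict[str, object] = {"id": p.id, **_cov_cells(p)}
            for j in range(1, kmax + 1):
                r = next((r for r in p.visit.readings if r.order_index == j), None)
                row[f"sbp{j}"] = r.systolic if r else ""
                row[f"dbp{j}"] = r.diastolic if r else ""
            for period, (cs, cd) in _ABPM_SUMMARY_COLS.items():
                m = p.abpm.summary_for(period)
                row[cs] = m.systolic if m else ""
                row[cd] = m.diastolic if m else ""
            rows.append(row)
    elif layout == "long":
        for p in cohort:
            cov = _cov_cells(p)
            for r in p.visit.readings:
                rows.append({"id": p.id, **cov, "reading_kind": "clinic",
                             "order_index": r.order_index,
                             "systolic": r.systolic, "diastolic": r.diastolic})
            for r in p.abpm.readings:
                rows.append({"id": p.id, **cov,
                             "reading_kind": f"abpm_{Period(r.period).value}",
                             "order_index": "",
                             "systolic": r.systolic, "diastolic": r.diastolic})
            for period, kind in ((Period.DAY, "abpm_day_mean"),
                                 (Period.NIGHT, "abpm_night_mean"),
                                 (Period.H24, "abpm_24h_mean")):
                m = p.abpm.summary_for(period)
                if m is not None:
                    rows.append({"id": p.id, **cov, "reading_kind": kind,
                                 "order_index": "",
                                 "systolic": m.systolic, "diastolic": m.diastolic})
    else:
        raise CohortSchemaError(f"unknown layout {layout!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Eligibility


def apply_eligibility(
    cohort: Cohort,
    required_covariates: Sequence[str] = DEFAULT_REQUIRED_COVARIATES,
    min_clinic_readings: int = 3,
    reference_period: Period | str = Period.DAY,
) -> tuple[Cohort, ExclusionLog]:
    """Apply the study eligibility filters.

    Retained patients have at least ``min_clinic_readings`` clinic readings,
    are adults, carry every covariate the configured prediction model needs,
    and have usable ABPM for the reference period.  Each excluded patient
    gets exactly one primary reason, assigned in the fixed precedence order
    missing BP -> under 18 -> missing clinical information -> ABPM not worn.
    """
    reference_period = Period(reference_period)
    eligible: list[PatientRecord] = []
    log = ExclusionLog()
    for p in cohort:
        if len(p.visit) < min_clinic_readings:
            reason = ExclusionReason.MISSING_BP
        elif p.age is not None and p.age < 18:
            reason = ExclusionReason.UNDER_18
        elif any(getattr(p, c) is None for c in required_covariates):
            reason = ExclusionReason.MISSING_CLINICAL_INFO
        elif not p.abpm.has_period(reference_period):
            reason = ExclusionReason.ABPM_NOT_WORN
        else:
            eligible.append(p)
            continue
        log.entries.append((p.id, reason))
        logger.info("excluded patient %s: %s", p.id, reason.value)
    return Cohort(eligible, provenance=cohort.provenance), log
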