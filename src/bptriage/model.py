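"""Out-of-office BP prediction and the three-way triage rule.

The prediction model is a pair of linear equations (systolic and diastolic)
over clinic-BP-derived regressors and patient covariates.  The triage rule
compares the predicted out-of-office BP with a band [lower, upper):
predictions below the lower bound on *both* components are classified
normotensive outright, predictions at or above the upper bound on *either*
component hypertensive outright, and everything in between is referred for
ABPM.  This OR/AND composition keeps the three groups exhaustive and
mutually exclusive.

Coefficients and bands are data, not code: they are loaded from a YAML
config (see ``bptriage/data/illustrative_model.yaml``).  The shipped set is
illustrative — to run the published triage model, transcribe its coefficient
values and referral band into a config of the same shape.
"""
from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Callable

import yaml

from .cohort import ClinicVisit, PatientRecord, Sex
from .exceptions import (
    InsufficientReadingsError,
    MissingCovariateError,
    ModelConfigError,
)
from .reference import BPThreshold, MeanBP

__all__ = [
    "MeanRule",
    "Term",
    "CoefficientSet",
    "TriageBands",
    "PredictedBP",
    "TriageDecision",
    "clinic_mean",
    "predict_out_of_office",
    "triage",
    "identity_coefficients",
    "load_model_config",
    "ModelConfig",
]


class MeanRule(str, enum.Enum):
    """Which clinic readings enter the visit mean."""

    ALL = "all"
    DROP_FIRST = "drop_first"
    LAST_TWO = "last_two"


_RULE_MIN = {MeanRule.ALL: 1, MeanRule.DROP_FIRST: 2, MeanRule.LAST_TWO: 2}


def clinic_mean(visit: ClinicVisit, rule: MeanRule | str = MeanRule.ALL) -> MeanBP:
    """Mean clinic BP over the subset of readings selected by ``rule``."""
    rule = MeanRule(rule)
    if len(visit) < _RULE_MIN[rule]:
        raise InsufficientReadingsError(
            f"rule {rule.value!r} needs >= {_RULE_MIN[rule]} readings, "
            f"visit has {len(visit)}"
        )
    readings = sorted(visit.readings, key=lambda r: r.order_index)
    if rule is MeanRule.DROP_FIRST:
        readings = readings[1:]
    elif rule is MeanRule.LAST_TWO:
        readings = readings[-2:]
    return MeanBP(
        systolic=fmean(r.systolic for r in readings),
        diastolic=fmean(r.diastolic for r in readings),
    )


class TriageDecision(str, enum.Enum):
    NORMOTENSIVE = "normotensive"
    HYPERTENSIVE = "hypertensive"
    REFER_ABPM = "refer_abpm"

    @property
    def rank(self) -> int:
        """Severity ordering: normotensive < refer_abpm < hypertensive."""
        return {"normotensive": 0, "refer_abpm": 1, "hypertensive": 2}[self.value]


@dataclass(frozen=True, slots=True)
class PredictedBP:
    """Predicted out-of-office BP.  Unlike measured summaries, a prediction
    with systolic <= diastolic is physiologically suspect but not an error
    (it can arise from extreme covariates); it triggers a warning."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.systolic) and math.isfinite(self.diastolic)):
            raise ValueError("prediction must be finite")
        if self.systolic <= self.diastolic:
            warnings.warn(
                f"predicted systolic {self.systolic:.1f} <= diastolic "
                f"{self.diastolic:.1f}; check model coefficients",
                stacklevel=3,
            )


@dataclass(frozen=True, slots=True)
class TriageBands:
    """Referral band: below ``lower`` (both components) is definitively
    normotensive; at/above ``upper`` (either component) definitively
    hypertensive; in between, refer for ABPM."""

    lower: BPThreshold
    upper: BPThreshold

    def __post_init__(self) -> None:
        if not (self.lower.systolic < self.upper.systolic
                and self.lower.diastolic < self.upper.diastolic):
            raise ModelConfigError("triage band lower must be below upper")


# --- covariate resolution ---------------------------------------------------

def _flag(value: bool | None, name: str, pid: str) -> float:
    if value is None:
        raise MissingCovariateError(name, pid)
    return 1.0 if value else 0.0


def _numeric(value: float | None, name: str, pid: str) -> float:
    if value is None:
        raise MissingCovariateError(name, pid)
    return float(value)


def _resolve_covariate(patient: PatientRecord, name: str,
                       rule: MeanRule) -> float:
    """Resolve a term's covariate name to a numeric regressor value."""
    pid = patient.id
    if name.startswith("clinic_"):
        mean = clinic_mean(patient.visit, rule)
        readings = sorted(patient.visit.readings, key=lambda r: r.order_index)
        derived: dict[str, Callable[[], float]] = {
            "clinic_sbp_mean": lambda: mean.systolic,
            "clinic_dbp_mean": lambda: mean.diastolic,
            "clinic_sbp_last": lambda: readings[-1].systolic,
            "clinic_dbp_last": lambda: readings[-1].diastolic,
            "clinic_sbp_range": lambda: (max(r.systolic for r in readings)
                                         - min(r.systolic for r in readings)),
            "clinic_dbp_range": lambda: (max(r.diastolic for r in readings)
                                         - min(r.diastolic for r in readings)),
        }
        if name not in derived:
            raise ModelConfigError(f"unknown clinic-derived regressor {name!r}")
        return derived[name]()
    if name == "age":
        return _numeric(patient.age, name, pid)
    if name == "bmi":
        return _numeric(patient.bmi, name, pid)
    if name == "n_antihypertensives":
        return _numeric(patient.n_antihypertensives, name, pid)
    if name == "sex_male":
        if patient.sex is None:
            raise MissingCovariateError("sex", pid)
        return 1.0 if patient.sex is Sex.MALE else 0.0
    if name == "sex_female":
        if patient.sex is None:
            raise MissingCovariateError("sex", pid)
        return 1.0 if patient.sex is Sex.FEMALE else 0.0
    if name == "treated":
        return _flag(patient.treated, "n_antihypertensives", pid)
    if name in ("diabetes", "ckd", "af", "cvd_history", "hypertension_diagnosis"):
        return _flag(getattr(patient, name), name, pid)
    raise ModelConfigError(f"unknown covariate {name!r}")


def _apply_transform(x: float, transform: str) -> float:
    """Transform grammar: ``identity``, ``center:<c>`` (x - c),
    ``scale:<c>`` (x / c), ``square``, ``log``."""
    if transform == "identity":
        return x
    if transform == "square":
        return x * x
    if transform == "log":
        if x <= 0:
            raise ModelConfigError(f"log transform of non-positive value {x}")
        return math.log(x)
    kind, sep, arg = transform.partition(":")
    if sep:
        try:
            c = float(arg)
        except ValueError:
            raise ModelConfigError(f"bad transform argument {transform!r}") from None
        if kind == "center":
            return x - c
        if kind == "scale":
            if c == 0:
                raise ModelConfigError("scale transform by zero")
            return x / c
    raise ModelConfigError(f"unknown transform descriptor {transform!r}")


@dataclass(frozen=True, slots=True)
class Term:
    """One regressor: covariate name, transform descriptor, and its
    coefficient in the systolic and diastolic equations."""

    covariate: str
    beta_systolic: float
    beta_diastolic: float
    transform: str = "identity"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta_systolic)
                and math.isfinite(self.beta_diastolic)):
            raise ModelConfigError(f"non-finite coefficient on {self.covariate!r}")


@dataclass(frozen=True, slots=True)
class CoefficientSet:
    """Linear model: prediction = intercept + sum(beta * transform(x))."""

    intercept_systolic: float
    intercept_diastolic: float
    terms: tuple[Term, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(
            t if isinstance(t, Term) else Term(**t) for t in self.terms
        ))

    @classmethod
    def from_dict(cls, data: dict) -> "CoefficientSet":
        try:
            return cls(
                intercept_systolic=float(data["intercept_systolic"]),
                intercept_diastolic=float(data["intercept_diastolic"]),
                terms=tuple(Term(**t) for t in data.get("terms", ())),
                name=data.get("name", ""),
            )
        except (KeyError, TypeError) as exc:
            raise ModelConfigError(f"bad coefficient config: {exc}") from exc


def identity_coefficients() -> CoefficientSet:
    """The identity model: predicted out-of-office BP = clinic visit mean.

    Useful as a baseline and for degenerate-case checks where the triage
    reduces to a fixed clinic threshold.
    """
    return CoefficientSet(
        intercept_systolic=0.0,
        intercept_diastolic=0.0,
        terms=(
            Term("clinic_sbp_mean", beta_systolic=1.0, beta_diastolic=0.0),
            Term("clinic_dbp_mean", beta_systolic=0.0, beta_diastolic=1.0),
        ),
        name="identity",
    )


def predict_out_of_office(
    patient: PatientRecord,
    coeffs: CoefficientSet,
    mean_rule: MeanRule | str = MeanRule.ALL,
) -> PredictedBP:
    """Evaluate the linear prediction equations for one patient.

    Raises :class:`MissingCovariateError` naming the absent covariate, or
    :class:`ModelConfigError` for an unknown covariate/transform.
    """
    mean_rule = MeanRule(mean_rule)
    s = coeffs.intercept_systolic
    d = coeffs.intercept_diastolic
    for term in coeffs.terms:
        x = _apply_transform(
            _resolve_covariate(patient, term.covariate, mean_rule),
            term.transform,
        )
        s += term.beta_systolic * x
        d += term.beta_diastolic * x
    return PredictedBP(s, d)


def triage(pred: PredictedBP, bands: TriageBands) -> TriageDecision:
    """Three-way triage of a predicted out-of-office BP."""
    if (pred.systolic >= bands.upper.systolic
            or pred.diastolic >= bands.upper.diastolic):
        return TriageDecision.HYPERTENSIVE
    if (pred.systolic < bands.lower.systolic
            and pred.diastolic < bands.lower.diastolic):
        return TriageDecision.NORMOTENSIVE
    return TriageDecision.REFER_ABPM


# --- config loading ---------------------------------------------------------

@dataclass(slots=True)
class ModelConfig:
    """Everything needed to run a triage strategy, as loaded from YAML."""

    coefficients: CoefficientSet
    bands: TriageBands
    mean_rule: MeanRule = MeanRule.ALL
    reference_thresholds: dict = field(default_factory=dict)


def _threshold_from(data) -> BPThreshold:
    if isinstance(data, dict):
        return BPThreshold(float(data["systolic"]), float(data["diastolic"]))
    s, d = data
    return BPThreshold(float(s), float(d))


def load_model_config(path: str | Path) -> ModelConfig:
    """Load coefficients, bands, mean rule and reference thresholds from a
    YAML file with top-level keys ``model`` and (optionally) ``reference``."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        model = data["model"]
        coeffs = CoefficientSet.from_dict(model["coefficients"])
        bands = TriageBands(
            lower=_threshold_from(model["bands"]["lower"]),
            upper=_threshold_from(model["bands"]["upper"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelConfigError(f"bad model config {path}: {exc}") from exc
    mean_rule = MeanRule(model.get("mean_rule", "all"))
    reference = {
        key: _threshold_from(val)
        for key, val in (data.get("reference") or {}).items()
    }
    return ModelConfig(coefficients=coeffs, bands=bands,
                       mean_rule=mean_rule, reference_thresholds=reference)
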