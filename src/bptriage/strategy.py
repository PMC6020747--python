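"""Apply a measurement strategy to a cohort and score it against ABPM.

A strategy assigns every patient a final binary hypertension class, either
directly or after referring them for ABPM.  Referred patients take their
final class from the reference-standard ABPM itself, so by construction they
can only be scored sustained hypertension or normotension; false positives
(white-coat) and false negatives (masked hypertension) arise exclusively
among patients the strategy classified without ABPM.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .cohort import Cohort
from .exceptions import MissingPeriodError, UndefinedMetricError
from .model import (
    CoefficientSet,
    MeanRule,
    TriageBands,
    TriageDecision,
    clinic_mean,
    predict_out_of_office,
    triage,
)
from .reference import (
    BPStatus,
    BPThreshold,
    DEFAULT_THRESHOLDS,
    Period,
    Phenotype,
    abpm_summary,
    bp_status,
    phenotype_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyKind",
    "StrategySpec",
    "FinalClassification",
    "ConfusionTable",
    "apply_strategy",
    "confusion_of",
    "utilisation",
    "unnecessary_treatment",
]


class StrategyKind(str, enum.Enum):
    PROOFBP_TRIAGE = "proofbp_triage"
    FIXED_THRESHOLD = "fixed_threshold"


@dataclass(frozen=True, slots=True)
class StrategySpec:
    """A strategy to evaluate.

    ``proofbp_triage`` needs ``coefficients`` and ``bands``;
    ``fixed_threshold`` needs ``clinic_threshold`` and implements the
    generic guideline pattern "clinic mean at/above threshold triggers ABPM
    confirmation (``confirm_with_abpm=True``) or a direct diagnosis".
    """

    kind: StrategyKind
    coefficients: CoefficientSet | None = None
    bands: TriageBands | None = None
    mean_rule: MeanRule = MeanRule.ALL
    clinic_threshold: BPThreshold | None = None
    confirm_with_abpm: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        kind = StrategyKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is StrategyKind.PROOFBP_TRIAGE:
            if self.coefficients is None or self.bands is None:
                raise ValueError("triage strategy needs coefficients and bands")
        else:
            if self.clinic_threshold is None:
                raise ValueError("fixed-threshold strategy needs clinic_threshold")

    def decide(self, patient) -> TriageDecision:
        """Per-patient decision before any ABPM resolution."""
        if self.kind is StrategyKind.PROOFBP_TRIAGE:
            pred = predict_out_of_office(patient, self.coefficients, self.mean_rule)
            return triage(pred, self.bands)
        mean = clinic_mean(patient.visit, self.mean_rule)
        raised = bp_status(mean, self.clinic_threshold) is BPStatus.HYPERTENSIVE
        if raised:
            return (TriageDecision.REFER_ABPM if self.confirm_with_abpm
                    else TriageDecision.HYPERTENSIVE)
        return TriageDecision.NORMOTENSIVE


@dataclass(frozen=True, slots=True)
class FinalClassification:
    """A patient's strategy decision, final class, and phenotype."""

    id: str
    decision: TriageDecision
    final_class: BPStatus
    used_abpm: bool
    phenotype: Phenotype

    def __post_init__(self) -> None:
        if self.used_abpm != (self.decision is TriageDecision.REFER_ABPM):
            raise ValueError("used_abpm must mirror a refer_abpm decision")


@dataclass(frozen=True, slots=True)
class ConfusionTable:
    """Phenotype counts: tp=sustained, tn=normotension, fp=white-coat,
    fn=masked hypertension."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.tp + other.tp, self.tn + other.tn,
                              self.fp + other.fp, self.fn + other.fn)


def apply_strategy(
    cohort: Cohort,
    spec: StrategySpec,
    reference_period: Period | str = Period.DAY,
    reference_threshold: BPThreshold | None = None,
) -> tuple[list[FinalClassification], list[tuple[str, str]]]:
    """Classify every patient and score against the reference-standard ABPM.

    Returns the classifications plus a list of (patient id, message) entries
    for patients dropped because the reference-period ABPM was unavailable.
    """
    reference_period = Period(reference_period)
    if reference_threshold is None:
        reference_threshold = DEFAULT_THRESHOLDS[reference_period]
    out: list[FinalClassification] = []
    dropped: list[tuple[str, str]] = []
    for patient in cohort:
        try:
            ref_mean, _ = abpm_summary(patient.abpm, reference_period)
        except MissingPeriodError as exc:
            dropped.append((patient.id, str(exc)))
            logger.warning("patient %s dropped from evaluation: %s",
                           patient.id, exc)
            continue
        ref_class = bp_status(ref_mean, reference_threshold)
        decision = spec.decide(patient)
        if decision is TriageDecision.REFER_ABPM:
            final = ref_class
            used_abpm = True
        else:
            final = (BPStatus.HYPERTENSIVE
                     if decision is TriageDecision.HYPERTENSIVE
                     else BPStatus.NORMOTENSIVE)
            used_abpm = False
        out.append(FinalClassification(
            id=patient.id,
            decision=decision,
            final_class=final,
            used_abpm=used_abpm,
            phenotype=phenotype_of(final, ref_class),
        ))
    return out, dropped


_PHENOTYPE_SLOT = {
    Phenotype.SUSTAINED_HYPERTENSION: "tp",
    Phenotype.NORMOTENSION: "tn",
    Phenotype.WHITE_COAT_HYPERTENSION: "fp",
    Phenotype.MASKED_HYPERTENSION: "fn",
}


def confusion_of(classifications: list[FinalClassification]) -> ConfusionTable:
    """Tally phenotypes into a confusion table."""
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for c in classifications:
        counts[_PHENOTYPE_SLOT[c.phenotype]] += 1
    return ConfusionTable(**counts)


def utilisation(classifications: list[FinalClassification],
                level: float = 0.95, ci_method: str = "wald"):
    """Proportion of patients referred for ABPM, with a binomial CI."""
    from .stats import proportion_estimate  # local import avoids a cycle

    n = len(classifications)
    if n == 0:
        raise UndefinedMetricError("utilisation of an empty classification list")
    k = sum(c.used_abpm for c in classifications)
    return proportion_estimate(k, n, level=level, method=ci_method)


def unnecessary_treatment(classifications: list[FinalClassification],
                          level: float = 0.95, ci_method: str = "wald"):
    """Patients who would be treated without needing it: white-coat
    phenotypes classified without ABPM.  The proportion uses the full cohort
    as denominator.  Returns ``(count, estimate)``."""
    from .stats import proportion_estimate

    n = len(classifications)
    k = sum((not c.used_abpm)
            and c.phenotype is Phenotype.WHITE_COAT_HYPERTENSION
            for c in classifications)
    if n == 0:
        return 0, None
    return k, proportion_estimate(k, n, level=level, method=ci_method)
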