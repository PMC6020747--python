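"""Diagnostic-accuracy statistics with confidence intervals.

All metrics are computed from a :class:`~bptriage.strategy.ConfusionTable`
whose cells are the four hypertension phenotypes (tp=sustained,
tn=normotension, fp=white-coat, fn=masked).  Point estimates are proportions
in [0, 1]; display helpers rescale to percent.

Confidence intervals default to the Wald normal approximation
``p +/- z*sqrt(p(1-p)/n)`` with bounds clipped to [0, 1]; Wilson and
Clopper-Pearson are available via ``method=`` and delegate to statsmodels.

For a binary test the AUROC reduces exactly to (sensitivity+specificity)/2
— the ROC curve is the two straight segments through the single operating
point — and its standard error is taken as
``0.5*sqrt(SE_sens^2 + SE_spec^2)`` (independent binomial sampling in the
diseased and non-diseased groups).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .exceptions import UndefinedMetricError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cohort import Cohort, PatientRecord
    from .strategy import ConfusionTable, FinalClassification

__all__ = [
    "Estimate",
    "wald_ci",
    "proportion_estimate",
    "sensitivity",
    "specificity",
    "predictive_values",
    "correct_proportion",
    "binary_auroc",
    "AccuracyReport",
    "accuracy_report",
    "SubgroupDefinition",
    "standard_subgroups",
    "subgroup_analysis",
    "format_accuracy_table",
]


@dataclass(frozen=True, slots=True)
class Estimate:
    """A point estimate with a confidence interval."""

    value: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower - 1e-12 <= self.value <= self.upper + 1e-12:
            raise ValueError(
                f"CI ({self.lower}, {self.upper}) does not contain {self.value}"
            )

    def pct(self, dp: int = 1) -> str:
        """Display as percentage, e.g. ``97.2 (95.8 to 98.5)``."""
        f = f"{{:.{dp}f}}"
        return (f"{f.format(100 * self.value)} "
                f"({f.format(100 * self.lower)} to {f.format(100 * self.upper)})")

    def fmt(self, dp: int = 2) -> str:
        """Display on the raw scale, e.g. ``0.86 (0.84 to 0.89)``."""
        f = f"{{:.{dp}f}}"
        return (f"{f.format(self.value)} "
                f"({f.format(self.lower)} to {f.format(self.upper)})")


def wald_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald normal-approximation CI for a binomial proportion, clipped to
    [0, 1]."""
    if n <= 0:
        raise UndefinedMetricError("Wald interval with n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def proportion_estimate(k: int, n: int, level: float = 0.95,
                        method: str = "wald") -> Estimate:
    """Binomial proportion with CI; ``method`` is ``wald`` (default),
    ``wilson``, or ``clopper_pearson``."""
    if n <= 0:
        raise UndefinedMetricError("proportion with n = 0")
    if method == "wald":
        lo, hi = wald_ci(k, n, level)
    elif method == "wilson":
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    elif method == "clopper_pearson":
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return Estimate(k / n, float(lo), float(hi), level)


def sensitivity(ct: "ConfusionTable", level: float = 0.95,
                method: str = "wald") -> Estimate:
    """tp / (tp + fn): the share of truly hypertensive patients detected."""
    if ct.tp + ct.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no hypertensive patients")
    return proportion_estimate(ct.tp, ct.tp + ct.fn, level, method)


def specificity(ct: "ConfusionTable", level: float = 0.95,
                method: str = "wald") -> Estimate:
    """tn / (tn + fp): the share of truly normotensive patients ruled out."""
    if ct.tn + ct.fp == 0:
        raise UndefinedMetricError("specificity undefined: no normotensive patients")
    return proportion_estimate(ct.tn, ct.tn + ct.fp, level, method)


def predictive_values(ct: "ConfusionTable", level: float = 0.95,
                      method: str = "wald") -> tuple[Estimate | None, Estimate | None]:
    """(PPV, NPV); either is ``None`` when its denominator is zero."""
    ppv = (proportion_estimate(ct.tp, ct.tp + ct.fp, level, method)
           if ct.tp + ct.fp > 0 else None)
    npv = (proportion_estimate(ct.tn, ct.tn + ct.fn, level, method)
           if ct.tn + ct.fn > 0 else None)
    return ppv, npv


def correct_proportion(ct: "ConfusionTable", level: float = 0.95,
                       method: str = "wald") -> Estimate:
    """(tp + tn) / n: the share with correctly classified status."""
    if ct.n == 0:
        raise UndefinedMetricError("correct proportion undefined on empty table")
    return proportion_estimate(ct.tp + ct.tn, ct.n, level, method)


def binary_auroc(ct: "ConfusionTable", level: float = 0.95) -> Estimate:
    """AUROC of a binary test: (sensitivity + specificity) / 2.

    The CI uses SE = 0.5*sqrt(SE_sens^2 + SE_spec^2), clipped to [0, 1].
    """
    n_pos, n_neg = ct.tp + ct.fn, ct.tn + ct.fp
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: one reference class absent")
    se_ = ct.tp / n_pos
    sp = ct.tn / n_neg
    auc = (se_ + sp) / 2
    se_sens = math.sqrt(se_ * (1 - se_) / n_pos)
    se_spec = math.sqrt(sp * (1 - sp) / n_neg)
    se_auc = 0.5 * math.sqrt(se_sens ** 2 + se_spec ** 2)
    z = norm.ppf(0.5 + level / 2)
    return Estimate(auc, max(0.0, auc - z * se_auc),
                    min(1.0, auc + z * se_auc), level)


@dataclass(frozen=True, slots=True)
class AccuracyReport:
    """Per-population accuracy summary; undefined metrics are ``None``."""

    n: int
    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None
    correct_proportion: Estimate | None
    auroc: Estimate | None
    utilisation: Estimate | None = None

    def to_dict(self) -> dict:
        def cell(e: Estimate | None):
            return None if e is None else {
                "value": e.value, "lower": e.lower, "upper": e.upper,
            }

        return {
            "n": self.n,
            "sensitivity": cell(self.sensitivity),
            "specificity": cell(self.specificity),
            "ppv": cell(self.ppv),
            "npv": cell(self.npv),
            "correct_proportion": cell(self.correct_proportion),
            "auroc": cell(self.auroc),
            "utilisation": cell(self.utilisation),
        }


def accuracy_report(ct: "ConfusionTable", n_referred: int | None = None,
                    level: float = 0.95, method: str = "wald") -> AccuracyReport:
    """Build a full accuracy report from a confusion table.

    ``n_referred`` (patients sent for ABPM) enables the utilisation row.
    Metrics with empty denominators are reported as ``None`` rather than
    0 or 1.
    """
    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedMetricError:
            return None

    ppv, npv = predictive_values(ct, level, method)
    util = (proportion_estimate(n_referred, ct.n, level, method)
            if n_referred is not None and ct.n > 0 else None)
    return AccuracyReport(
        n=ct.n,
        sensitivity=safe(sensitivity, ct, level, method),
        specificity=safe(specificity, ct, level, method),
        ppv=ppv,
        npv=npv,
        correct_proportion=safe(correct_proportion, ct, level, method),
        auroc=safe(binary_auroc, ct, level),
        utilisation=util,
    )


@dataclass(frozen=True, slots=True)
class SubgroupDefinition:
    """A named partition of the cohort.

    ``stratum_of`` maps a patient record to a stratum label; patients with
    the relevant covariate missing go to an explicit ``unknown`` stratum so
    the strata always partition the cohort.
    """

    name: str
    stratum_of: Callable[["PatientRecord"], str]


def _binary_stratum(attr: str, yes: str, no: str):
    def f(p) -> str:
        v = getattr(p, attr)
        return "unknown" if v is None else (yes if v else no)
    return f


def standard_subgroups() -> list[SubgroupDefinition]:
    """The conventional subgroup set: care setting, age 65, sex, current
    smoking, BMI 30, and histories of hypertension, diabetes, CKD and CVD."""
    from .cohort import Smoking

    def setting(p):
        return "unknown" if p.setting is None else p.setting.value

    def age(p):
        return "unknown" if p.age is None else ("<65" if p.age < 65 else ">=65")

    def sex(p):
        return "unknown" if p.sex is None else p.sex.value

    def smoking(p):
        if p.smoking is Smoking.UNKNOWN:
            return "unknown"
        return "current" if p.smoking is Smoking.CURRENT else "never_or_former"

    def bmi(p):
        return "unknown" if p.bmi is None else ("<30" if p.bmi < 30 else ">=30")

    return [
        SubgroupDefinition("setting", setting),
        SubgroupDefinition("age", age),
        SubgroupDefinition("sex", sex),
        SubgroupDefinition("smoking", smoking),
        SubgroupDefinition("bmi", bmi),
        SubgroupDefinition("hypertension_diagnosis",
                           _binary_stratum("hypertension_diagnosis",
                                           "diagnosed", "not_diagnosed")),
        SubgroupDefinition("diabetes", _binary_stratum("diabetes", "yes", "no")),
        SubgroupDefinition("ckd", _binary_stratum("ckd", "yes", "no")),
        SubgroupDefinition("cvd_history",
                           _binary_stratum("cvd_history", "yes", "no")),
    ]


def subgroup_analysis(
    classifications: Sequence["FinalClassification"],
    cohort: "Cohort",
    definitions: Iterable[SubgroupDefinition],
    level: float = 0.95,
    method: str = "wald",
) -> dict[str, dict[str, AccuracyReport]]:
    """Accuracy reports per stratum for each subgroup definition.

    Every classified patient lands in exactly one stratum per definition, so
    stratum confusion tables sum to the overall table.
    """
    from .strategy import confusion_of

    patients = cohort.by_id()
    out: dict[str, dict[str, AccuracyReport]] = {}
    for definition in definitions:
        groups: dict[str, list] = {}
        for c in classifications:
            label = definition.stratum_of(patients[c.id])
            groups.setdefault(label, []).append(c)
        out[definition.name] = {
            label: accuracy_report(
                confusion_of(cls),
                n_referred=sum(c.used_abpm for c in cls),
                level=level, method=method,
            )
            for label, cls in sorted(groups.items())
        }
    return out


def format_accuracy_table(reports: Mapping[str, AccuracyReport]) -> str:
    """Aligned plain-text accuracy table, percentages to one decimal."""
    rows = []
    for name, r in reports.items():
        rows.append({
            "Population": name,
            "N": r.n,
            "AUROC (95% CI)": r.auroc.fmt(2) if r.auroc else "-",
            "Sensitivity": r.sensitivity.pct(1) if r.sensitivity else "-",
            "Specificity": r.specificity.pct(1) if r.specificity else "-",
            "PPV": r.ppv.pct(1) if r.ppv else "-",
            "NPV": r.npv.pct(1) if r.npv else "-",
            "Correct": (r.correct_proportion.pct(1)
                        if r.correct_proportion else "-"),
            "ABPM use": r.utilisation.pct(1) if r.utilisation else "-",
        })
    return pd.DataFrame(rows).to_string(index=False)
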