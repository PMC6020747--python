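"""Reference-standard blood pressure status and hypertension phenotyping.

The reference standard throughout is the mean daytime ambulatory blood
pressure (ABPM), dichotomised at a guideline threshold (default
135/85 mm Hg).  A strategy's binary call crossed with the reference call
yields one of four phenotypes:

* sustained hypertension  — raised on both (a true positive),
* white-coat hypertension — raised by the strategy only (a false positive),
* masked hypertension     — raised on ABPM only (a false negative),
* normotension            — raised on neither (a true negative).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .exceptions import MissingPeriodError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cohort import AbpmSession

__all__ = [
    "Period",
    "MeanBP",
    "BPThreshold",
    "BPStatus",
    "Phenotype",
    "DEFAULT_THRESHOLDS",
    "abpm_summary",
    "bp_status",
    "phenotype_of",
]


class Period(str, enum.Enum):
    """ABPM monitoring period."""

    DAY = "day"
    NIGHT = "night"
    H24 = "h24"


class BPStatus(str, enum.Enum):
    HYPERTENSIVE = "hypertensive"
    NORMOTENSIVE = "normotensive"


class Phenotype(str, enum.Enum):
    SUSTAINED_HYPERTENSION = "sustained_hypertension"
    WHITE_COAT_HYPERTENSION = "white_coat_hypertension"
    MASKED_HYPERTENSION = "masked_hypertension"
    NORMOTENSION = "normotension"


@dataclass(frozen=True, slots=True)
class MeanBP:
    """A systolic/diastolic blood pressure summary in mm Hg."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.systolic) and math.isfinite(self.diastolic)):
            raise ValueError("blood pressure must be finite")
        if not self.systolic > self.diastolic > 0:
            raise ValueError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic}"
            )


@dataclass(frozen=True, slots=True)
class BPThreshold:
    """A diagnostic threshold; a mean is hypertensive when either component
    reaches its threshold (inclusive)."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > 0 and self.diastolic > 0):
            raise ValueError("thresholds must be positive")


#: Guideline thresholds per ABPM period.  Daytime 135/85 is the reference
#: standard; night and 24 h values are the conventional guideline figures
#: used in sensitivity analyses and are configurable.
DEFAULT_THRESHOLDS: dict[Period, BPThreshold] = {
    Period.DAY: BPThreshold(135.0, 85.0),
    Period.NIGHT: BPThreshold(120.0, 70.0),
    Period.H24: BPThreshold(130.0, 80.0),
}


def abpm_summary(session: "AbpmSession", period: Period | str = Period.DAY,
                 ) -> tuple[MeanBP, int | None]:
    """Mean ABPM for one period, with the number of contributing readings.

    A precomputed summary stored on the session takes precedence over raw
    readings; in that case the reading count is ``None``.  The 24 h summary
    derived from raw readings pools day and night readings.

    Raises
    ------
    MissingPeriodError
        If the session has neither raw readings nor a summary for ``period``.
    """
    period = Period(period)
    pre = session.summary_for(period)
    if pre is not None:
        return pre, None
    if period is Period.H24:
        readings = list(session.readings)
    else:
        readings = [r for r in session.readings if Period(r.period) is period]
    if not readings:
        raise MissingPeriodError(
            f"no ABPM readings or summary for period {period.value!r}"
        )
    n = len(readings)
    mean = MeanBP(
        systolic=sum(r.systolic for r in readings) / n,
        diastolic=sum(r.diastolic for r in readings) / n,
    )
    return mean, n


def bp_status(mean_bp: MeanBP, threshold: BPThreshold) -> BPStatus:
    """Dichotomise a BP summary: hypertensive iff systolic >= threshold
    systolic OR diastolic >= threshold diastolic (either-component rule)."""
    if (mean_bp.systolic >= threshold.systolic
            or mean_bp.diastolic >= threshold.diastolic):
        return BPStatus.HYPERTENSIVE
    return BPStatus.NORMOTENSIVE


_PHENOTYPE_MAP = {
    (BPStatus.HYPERTENSIVE, BPStatus.HYPERTENSIVE): Phenotype.SUSTAINED_HYPERTENSION,
    (BPStatus.HYPERTENSIVE, BPStatus.NORMOTENSIVE): Phenotype.WHITE_COAT_HYPERTENSION,
    (BPStatus.NORMOTENSIVE, BPStatus.HYPERTENSIVE): Phenotype.MASKED_HYPERTENSION,
    (BPStatus.NORMOTENSIVE, BPStatus.NORMOTENSIVE): Phenotype.NORMOTENSION,
}


def phenotype_of(strategy_class: BPStatus, reference_class: BPStatus) -> Phenotype:
    """Map a (strategy, reference) pair of binary calls to its phenotype."""
    return _PHENOTYPE_MAP[(BPStatus(strategy_class), BPStatus(reference_class))]
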