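"""Published summary data and fixture reconstruction.

The triage strategy was prospectively validated in a UK cohort of 887
consecutive patients referred for ABPM in routine primary and secondary
care.  The individual-level data are not public, but the study reports the
complete phenotype counts (confusion tables) and ABPM referral counts,
overall and split by whether the patient already had a hypertension
diagnosis ("management" stratum) or not ("diagnosis" stratum).  Those
printed counts are inputs here: every headline accuracy statistic is exactly
recomputable from them.

:func:`reconstruct_classifications` expands a confusion table and referral
count back into per-patient classification records (and minimal synthetic
patient records) so that the cohort-level machinery — confusion tallying,
utilisation, subgroup analysis — can be exercised on the published numbers.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .cohort import AbpmSession, ClinicReading, ClinicVisit, Cohort, PatientRecord
from .model import ModelConfig, TriageDecision, load_model_config
from .reference import BPStatus, MeanBP, Phenotype
from .strategy import ConfusionTable, FinalClassification

__all__ = [
    "StratumCounts",
    "validation_counts",
    "reconstruct_classifications",
    "reconstruct_validation_cohort",
    "illustrative_model_config",
]


@dataclass(frozen=True, slots=True)
class StratumCounts:
    """Published counts for one population stratum."""

    table: ConfusionTable
    n_referred: int

    @property
    def n(self) -> int:
        return self.table.n


def validation_counts() -> dict[str, StratumCounts]:
    """Phenotype and referral counts from the published external validation
    cohort (n=887), overall and by hypertension-diagnosis history."""
    return {
        "overall": StratumCounts(ConfusionTable(tp=584, tn=217, fp=69, fn=17),
                                 n_referred=435),
        "diagnosis": StratumCounts(ConfusionTable(tp=156, tn=88, fp=16, fn=8),
                                   n_referred=165),
        "management": StratumCounts(ConfusionTable(tp=428, tn=129, fp=53, fn=9),
                                    n_referred=270),
    }


_PHENOTYPE_FINAL = {
    Phenotype.SUSTAINED_HYPERTENSION: BPStatus.HYPERTENSIVE,
    Phenotype.WHITE_COAT_HYPERTENSION: BPStatus.HYPERTENSIVE,
    Phenotype.MASKED_HYPERTENSION: BPStatus.NORMOTENSIVE,
    Phenotype.NORMOTENSION: BPStatus.NORMOTENSIVE,
}


def reconstruct_classifications(
    counts: StratumCounts, id_prefix: str = "p",
) -> list[FinalClassification]:
    """Expand stratum counts into per-patient classification records.

    Referred patients can only be sustained or normotensive (their final
    class is the ABPM result itself), so the referrals are assigned to those
    two phenotypes, split proportionally.  Which individual gets which label
    is unidentifiable from the published counts and irrelevant to every
    count-based statistic.
    """
    ct, referred = counts.table, counts.n_referred
    if referred > ct.tp + ct.tn:
        raise ValueError("more referrals than sustained+normotensive patients")
    ref_tp = min(ct.tp, round(referred * ct.tp / (ct.tp + ct.tn)))
    ref_tn = referred - ref_tp
    if ref_tn > ct.tn:
        ref_tn, ref_tp = ct.tn, referred - ct.tn

    blocks = [
        (Phenotype.SUSTAINED_HYPERTENSION, ref_tp, True),
        (Phenotype.SUSTAINED_HYPERTENSION, ct.tp - ref_tp, False),
        (Phenotype.NORMOTENSION, ref_tn, True),
        (Phenotype.NORMOTENSION, ct.tn - ref_tn, False),
        (Phenotype.WHITE_COAT_HYPERTENSION, ct.fp, False),
        (Phenotype.MASKED_HYPERTENSION, ct.fn, False),
    ]
    out: list[FinalClassification] = []
    i = 0
    for phenotype, count, used_abpm in blocks:
        for _ in range(count):
            i += 1
            final = _PHENOTYPE_FINAL[phenotype]
            if used_abpm:
                decision = TriageDecision.REFER_ABPM
            else:
                decision = (TriageDecision.HYPERTENSIVE
                            if final is BPStatus.HYPERTENSIVE
                            else TriageDecision.NORMOTENSIVE)
            out.append(FinalClassification(
                id=f"{id_prefix}{i:04d}", decision=decision,
                final_class=final, used_abpm=used_abpm, phenotype=phenotype))
    return out


def _minimal_patient(pid: str, hypertension_diagnosis: bool) -> PatientRecord:
    """A synthetic placeholder record carrying only the stratifying flag;
    BP values are arbitrary valid numbers, not data."""
    visit = ClinicVisit((ClinicReading(140.0, 90.0, 1),
                         ClinicReading(138.0, 88.0, 2),
                         ClinicReading(136.0, 86.0, 3)))
    return PatientRecord(
        id=pid, visit=visit,
        abpm=AbpmSession(daytime_mean=MeanBP(138.0, 84.0)),
        hypertension_diagnosis=hypertension_diagnosis,
    )


def reconstruct_validation_cohort() -> tuple[Cohort, list[FinalClassification]]:
    """Patient-level reconstruction of the published validation results:
    classification records for both diagnosis strata plus matching synthetic
    patient records (the stratifying flag is real; BP values are filler)."""
    counts = validation_counts()
    cls_diag = reconstruct_classifications(counts["diagnosis"], id_prefix="d")
    cls_mgmt = reconstruct_classifications(counts["management"], id_prefix="m")
    patients = [
        _minimal_patient(c.id, hypertension_diagnosis=False) for c in cls_diag
    ] + [
        _minimal_patient(c.id, hypertension_diagnosis=True) for c in cls_mgmt
    ]
    return Cohort(patients, provenance="reconstructed from published counts"), \
        cls_diag + cls_mgmt


def illustrative_model_config() -> ModelConfig:
    """Load the shipped illustrative coefficient/band config."""
    ref = resources.files("bptriage").joinpath("data/illustrative_model.yaml")
    with resources.as_file(ref) as path:
        return load_model_config(Path(path))
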