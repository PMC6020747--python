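"""Strategy application, referral resolution, and confusion tables."""
import pytest

from bptriage import (
    BPStatus,
    BPThreshold,
    Cohort,
    ConfusionTable,
    Phenotype,
    SimulationParams,
    StrategyKind,
    StrategySpec,
    TriageBands,
    TriageDecision,
    abpm_summary,
    apply_strategy,
    bp_status,
    clinic_mean,
    confusion_of,
    identity_coefficients,
    phenotype_of,
    simulate_cohort,
    unnecessary_treatment,
    utilisation,
)
from bptriage.datasets import (
    reconstruct_classifications,
    validation_counts,
)
from conftest import make_patient

REF = BPThreshold(135, 85)
EPS = 1e-9


def triage_spec(lower=(130, 80), upper=(145, 90)):
    return StrategySpec(
        kind=StrategyKind.PROOFBP_TRIAGE,
        coefficients=identity_coefficients(),
        bands=TriageBands(BPThreshold(*lower), BPThreshold(*upper)),
    )


#: collapsed band: the three-way rule degenerates to a two-way 135/85 cut
COLLAPSED = triage_spec(lower=(135 - EPS, 85 - EPS), upper=(135, 85))
#: band so wide every realistic prediction falls inside it
ALL_REFERRED = triage_spec(lower=(20, 10), upper=(400, 300))


@pytest.fixture(scope="module")
def sim500():
    cohort, _ = simulate_cohort(SimulationParams(n=500, seed=11))
    return cohort


class TestApplyStrategy:
    def test_all_referred_yields_no_misclassification(self, sim500):
        cls, dropped = apply_strategy(sim500, ALL_REFERRED)
        assert not dropped
        assert all(c.used_abpm for c in cls)
        assert {c.phenotype for c in cls} <= {
            Phenotype.SUSTAINED_HYPERTENSION, Phenotype.NORMOTENSION}
        ct = confusion_of(cls)
        assert ct.fp == ct.fn == 0 and ct.n == len(sim500)

    def test_collapsed_band_reduces_to_clinic_vs_abpm_crossclass(self, sim500):
        """With an identity model and a collapsed band, phenotypes are the
        plain clinic-mean vs ABPM cross-classification."""
        cls, _ = apply_strategy(sim500, COLLAPSED)
        by_id = sim500.by_id()
        for c in cls:
            p = by_id[c.id]
            expected = phenotype_of(
                bp_status(clinic_mean(p.visit), REF),
                bp_status(abpm_summary(p.abpm, "day")[0], REF),
            )
            assert c.phenotype is expected
            assert not c.used_abpm

    def test_collapsed_band_equals_fixed_threshold_comparator(self, sim500):
        """Degenerate triage band == the generic fixed-threshold strategy
        that diagnoses directly from the clinic mean."""
        fixed = StrategySpec(kind=StrategyKind.FIXED_THRESHOLD,
                             clinic_threshold=REF, confirm_with_abpm=False)
        a, _ = apply_strategy(sim500, COLLAPSED)
        b, _ = apply_strategy(sim500, fixed)
        assert [(c.id, c.final_class, c.phenotype) for c in a] == \
               [(c.id, c.final_class, c.phenotype) for c in b]

    def test_confusion_counts_match_brute_force_recount(self, sim500):
        spec = triage_spec()
        cls, _ = apply_strategy(sim500, spec)
        ct = confusion_of(cls)
        # independent loop: recompute every patient's phenotype from scratch
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        by_id = sim500.by_id()
        for c in cls:
            p = by_id[c.id]
            ref_hyper = bp_status(abpm_summary(p.abpm, "day")[0], REF)
            mean = clinic_mean(p.visit)
            if mean.systolic >= 145 or mean.diastolic >= 90:
                strat = BPStatus.HYPERTENSIVE
            elif mean.systolic < 130 and mean.diastolic < 80:
                strat = BPStatus.NORMOTENSIVE
            else:
                strat = ref_hyper  # referred: final class is the ABPM result
            key = {
                (BPStatus.HYPERTENSIVE, BPStatus.HYPERTENSIVE): "tp",
                (BPStatus.NORMOTENSIVE, BPStatus.NORMOTENSIVE): "tn",
                (BPStatus.HYPERTENSIVE, BPStatus.NORMOTENSIVE): "fp",
                (BPStatus.NORMOTENSIVE, BPStatus.HYPERTENSIVE): "fn",
            }[(strat, ref_hyper)]
            tally[key] += 1
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"])

    def test_referred_patients_contribute_zero_fp_fn(self, sim500):
        cls, _ = apply_strategy(sim500, triage_spec())
        for c in cls:
            if c.used_abpm:
                assert c.phenotype in (Phenotype.SUSTAINED_HYPERTENSION,
                                       Phenotype.NORMOTENSION)

    def test_patient_without_reference_abpm_dropped_with_entry(self):
        cohort = Cohort([
            make_patient("ok"),
            make_patient("noabpm", abpm_day=None),
        ])
        cls, dropped = apply_strategy(cohort, triage_spec())
        assert [c.id for c in cls] == ["ok"]
        assert dropped[0][0] == "noabpm"

    def test_night_reference_uses_night_threshold(self):
        p = make_patient(
            "p", abpm_day=None,
            abpm_readings=[(138, 84, "day"), (122, 72, "night")])
        cls, _ = apply_strategy(Cohort([p]), ALL_REFERRED,
                                reference_period="night")
        # 122/72 >= 120/70 night threshold -> hypertensive reference
        assert cls[0].final_class is BPStatus.HYPERTENSIVE

    def test_widening_band_increases_utilisation_reduces_errors(self, sim500):
        narrow, _ = apply_strategy(sim500, triage_spec((133, 83), (140, 87)))
        wide, _ = apply_strategy(sim500, triage_spec((125, 75), (150, 95)))
        assert (sum(c.used_abpm for c in wide)
                >= sum(c.used_abpm for c in narrow))
        ct_n, ct_w = confusion_of(narrow), confusion_of(wide)
        assert ct_w.fp + ct_w.fn <= ct_n.fp + ct_n.fn


class TestConfusionOf:
    def test_published_overall_distribution(self):
        counts = validation_counts()["overall"]
        cls = reconstruct_classifications(counts)
        assert confusion_of(cls) == ConfusionTable(tp=584, tn=217, fp=69, fn=17)

    def test_empty_list_gives_zero_table(self):
        ct = confusion_of([])
        assert (ct.tp, ct.tn, ct.fp, ct.fn, ct.n) == (0, 0, 0, 0, 0)

    def test_counts_match_brute_force_tally(self, sim500):
        cls, _ = apply_strategy(sim500, triage_spec())
        ct = confusion_of(cls)
        assert ct.n == len(cls)
        for phenotype, cell in [
            (Phenotype.SUSTAINED_HYPERTENSION, ct.tp),
            (Phenotype.NORMOTENSION, ct.tn),
            (Phenotype.WHITE_COAT_HYPERTENSION, ct.fp),
            (Phenotype.MASKED_HYPERTENSION, ct.fn),
        ]:
            assert cell == sum(c.phenotype is phenotype for c in cls)


class TestUtilisation:
    def test_overall_referral_rate(self):
        cls = reconstruct_classifications(validation_counts()["overall"])
        est = utilisation(cls)
        assert est.value == pytest.approx(435 / 887)
        assert est.pct(1) == "49.0 (45.8 to 52.3)"

    def test_all_referred_is_100_percent(self, sim500):
        cls, _ = apply_strategy(sim500, ALL_REFERRED)
        assert utilisation(cls).value == 1.0

    def test_diagnosis_stratum_referral_rate(self):
        cls = reconstruct_classifications(validation_counts()["diagnosis"])
        assert utilisation(cls).value == pytest.approx(165 / 268)
        assert round(100 * utilisation(cls).value) == 62


class TestUnnecessaryTreatment:
    def test_published_counts(self):
        cls = reconstruct_classifications(validation_counts()["overall"])
        k, est = unnecessary_treatment(cls)
        assert k == 69
        assert est.value == pytest.approx(69 / 887)
        assert round(100 * est.lower) == 6 and round(100 * est.upper) == 10

    def test_all_referred_cohort_has_none(self, sim500):
        cls, _ = apply_strategy(sim500, ALL_REFERRED)
        assert unnecessary_treatment(cls)[0] == 0

    def test_equals_brute_force_count(self, sim500):
        cls, _ = apply_strategy(sim500, triage_spec())
        k, _ = unnecessary_treatment(cls)
        assert k == sum(
            (not c.used_abpm)
            and c.phenotype is Phenotype.WHITE_COAT_HYPERTENSION
            for c in cls)


def test_used_abpm_must_mirror_decision():
    from bptriage import FinalClassification

    with pytest.raises(ValueError):
        FinalClassification(
            id="x", decision=TriageDecision.REFER_ABPM,
            final_class=BPStatus.HYPERTENSIVE, used_abpm=False,
            phenotype=Phenotype.SUSTAINED_HYPERTENSION)
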