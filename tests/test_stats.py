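"""Accuracy metrics, confidence intervals, binary AUROC, subgroups."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from bptriage import (
    Cohort,
    ConfusionTable,
    SubgroupDefinition,
    accuracy_report,
    binary_auroc,
    correct_proportion,
    predictive_values,
    proportion_estimate,
    sensitivity,
    specificity,
    subgroup_analysis,
    wald_ci,
)
from bptriage.datasets import reconstruct_classifications, validation_counts
from bptriage.exceptions import UndefinedMetricError
from conftest import make_patient

tables = st.builds(
    ConfusionTable,
    tp=st.integers(0, 500), tn=st.integers(0, 500),
    fp=st.integers(0, 500), fn=st.integers(0, 500),
)


class TestPointEstimates:
    def test_overall_metrics(self, overall_ct):
        assert sensitivity(overall_ct).value == pytest.approx(584 / 601)
        assert specificity(overall_ct).value == pytest.approx(217 / 286)
        ppv, npv = predictive_values(overall_ct)
        assert ppv.value == pytest.approx(584 / 653)
        assert npv.value == pytest.approx(217 / 234)
        assert correct_proportion(overall_ct).value == pytest.approx(801 / 887)

    def test_management_stratum_sensitivity(self):
        ct = ConfusionTable(428, 129, 53, 9)
        assert round(100 * sensitivity(ct).value, 1) == 97.9

    def test_diagnosis_stratum_specificity(self):
        ct = ConfusionTable(156, 88, 16, 8)
        assert round(100 * specificity(ct).value, 1) == 84.6

    def test_degenerate_tables(self):
        assert sensitivity(ConfusionTable(5, 0, 0, 0)).value == 1.0
        assert specificity(ConfusionTable(0, 5, 0, 0)).value == 1.0
        perfect = ConfusionTable(10, 10, 0, 0)
        ppv, npv = predictive_values(perfect)
        assert (ppv.value, npv.value) == (1.0, 1.0)

    def test_undefined_metrics_raise_or_mark_none(self):
        no_pos = ConfusionTable(0, 10, 5, 0)
        with pytest.raises(UndefinedMetricError):
            sensitivity(no_pos)
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionTable(10, 0, 0, 5))
        ppv, npv = predictive_values(ConfusionTable(0, 10, 0, 5))
        assert ppv is None and npv is not None
        report = accuracy_report(no_pos)
        assert report.sensitivity is None and report.auroc is None

    def test_small_table_hand_arithmetic(self):
        ct = ConfusionTable(tp=7, tn=5, fp=3, fn=2)
        ppv, npv = predictive_values(ct)
        assert ppv.value == pytest.approx(0.7)
        assert npv.value == pytest.approx(5 / 7)
        assert sensitivity(ct).value == pytest.approx(7 / 9)
        assert specificity(ct).value == pytest.approx(5 / 8)

    @given(tables)
    def test_accuracy_identity(self, ct):
        """(tp+tn)/n == Se*prevalence + Sp*(1-prevalence)."""
        if ct.n == 0 or ct.tp + ct.fn == 0 or ct.tn + ct.fp == 0:
            return
        prev = (ct.tp + ct.fn) / ct.n
        lhs = correct_proportion(ct).value
        rhs = (sensitivity(ct).value * prev
               + specificity(ct).value * (1 - prev))
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestWaldCI:
    @pytest.mark.parametrize(
        "k, n, expected, dp",
        [
            (801, 887, (88, 92), 0),        # printed as integer percent
            (584, 601, (95.8, 98.5), 1),
            (217, 286, (70.9, 80.8), 1),
            (435, 887, (46, 52), 0),
        ],
    )
    def test_reproduces_printed_intervals(self, k, n, expected, dp):
        lo, hi = wald_ci(k, n)
        assert round(100 * lo, dp) == expected[0]
        assert round(100 * hi, dp) == expected[1]

    def test_degenerate_zero_successes_clips_to_zero(self):
        assert wald_ci(0, 10) == (0.0, 0.0)

    def test_zero_trials_undefined(self):
        with pytest.raises(UndefinedMetricError):
            wald_ci(3, 0)

    @pytest.mark.parametrize("k,n", [(801, 887), (50, 100), (3, 30)])
    def test_agrees_with_statsmodels_normal(self, k, n):
        lo, hi = wald_ci(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="normal")
        assert lo == pytest.approx(max(0.0, sm_lo), abs=1e-12)
        assert hi == pytest.approx(min(1.0, sm_hi), abs=1e-12)

    def test_alternative_methods_delegate_to_statsmodels(self):
        wilson = proportion_estimate(584, 601, method="wilson")
        beta = proportion_estimate(584, 601, method="clopper_pearson")
        assert (wilson.lower, wilson.upper) == pytest.approx(
            proportion_confint(584, 601, method="wilson"))
        assert (beta.lower, beta.upper) == pytest.approx(
            proportion_confint(584, 601, method="beta"))
        # the Wald interval is the one matching the printed 95.8-98.5
        assert round(100 * wilson.lower, 1) != 95.8

    def test_width_scales_as_inverse_root_n(self):
        """Quadrupling n at fixed p halves the Wald width (within 1%)."""
        lo1, hi1 = wald_ci(30, 100)
        lo2, hi2 = wald_ci(120, 400)
        assert (hi1 - lo1) / (hi2 - lo2) == pytest.approx(2.0, rel=0.01)

    def test_shrinks_with_n_at_fixed_p(self):
        widths = [np.diff(wald_ci(3 * m, 10 * m))[0] for m in (1, 4, 16, 64)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestBinaryAuroc:
    def test_overall_value_and_interval(self, overall_ct):
        est = binary_auroc(overall_ct)
        assert est.value == pytest.approx((584 / 601 + 217 / 286) / 2)
        assert round(est.lower, 2) == 0.84
        assert round(est.upper, 2) == 0.89

    def test_diagnosis_stratum_value(self):
        est = binary_auroc(ConfusionTable(156, 88, 16, 8))
        assert round(est.value, 2) == 0.90
        assert round(est.lower, 2) == 0.86 and round(est.upper, 2) == 0.94

    def test_one_class_absent_undefined(self):
        with pytest.raises(UndefinedMetricError):
            binary_auroc(ConfusionTable(0, 10, 5, 0))

    @given(tables)
    def test_equals_rank_statistic_oracle(self, ct):
        """(Se+Sp)/2 == the empirical Mann-Whitney AUROC on the expanded
        0/1 predictor/outcome pairs."""
        if ct.tp + ct.fn == 0 or ct.tn + ct.fp == 0:
            return
        y_true = [1] * (ct.tp + ct.fn) + [0] * (ct.tn + ct.fp)
        y_pred = ([1] * ct.tp + [0] * ct.fn
                  + [0] * ct.tn + [1] * ct.fp)
        assert binary_auroc(ct).value == pytest.approx(
            roc_auc_score(y_true, y_pred), abs=1e-12)


class TestSubgroups:
    def test_single_all_inclusive_stratum_equals_overall(self, overall_ct):
        cls = reconstruct_classifications(validation_counts()["overall"])
        cohort = Cohort([make_patient(c.id) for c in cls])
        table = subgroup_analysis(
            cls, cohort, [SubgroupDefinition("all", lambda p: "everyone")])
        report = table["all"]["everyone"]
        assert report.n == 887
        assert report.sensitivity.value == sensitivity(overall_ct).value
        assert report.utilisation.value == pytest.approx(435 / 887)

    def test_random_split_confusion_tables_sum_to_overall(self):
        rng = np.random.default_rng(3)
        cls = reconstruct_classifications(validation_counts()["overall"])
        flip = {c.id: bool(rng.integers(2)) for c in cls}
        cohort = Cohort([make_patient(c.id, diabetes=flip[c.id]) for c in cls])
        table = subgroup_analysis(
            cls, cohort,
            [SubgroupDefinition("coin",
                                lambda p: "heads" if p.diabetes else "tails")])
        strata = table["coin"]
        assert sum(r.n for r in strata.values()) == 887
        from bptriage import confusion_of

        by_stratum = {}
        for c in cls:
            label = "heads" if flip[c.id] else "tails"
            by_stratum.setdefault(label, []).append(c)
        summed = sum(
            (confusion_of(v) for v in by_stratum.values()),
            ConfusionTable(0, 0, 0, 0))
        assert summed == ConfusionTable(584, 217, 69, 17)

    def test_unknown_stratum_is_explicit(self):
        cls = reconstruct_classifications(validation_counts()["diagnosis"])
        cohort = Cohort([make_patient(c.id, diabetes=None) for c in cls])
        table = subgroup_analysis(
            cls, cohort,
            [SubgroupDefinition(
                "diabetes",
                lambda p: "unknown" if p.diabetes is None
                else ("yes" if p.diabetes else "no"))])
        assert set(table["diabetes"]) == {"unknown"}
        assert table["diabetes"]["unknown"].n == 268


def test_estimate_display_rounding_matches_published_tables(overall_ct):
    """1-dp percent formatting reproduces the published accuracy row."""
    assert sensitivity(overall_ct).pct(1) == "97.2 (95.8 to 98.5)"
    assert specificity(overall_ct).pct(1) == "75.9 (70.9 to 80.8)"
    ppv, npv = predictive_values(overall_ct)
    assert ppv.pct(1) == "89.4 (87.1 to 91.8)"
    assert npv.pct(1) == "92.7 (89.4 to 96.1)"
    assert correct_proportion(overall_ct).pct(1) == "90.3 (88.4 to 92.3)"
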