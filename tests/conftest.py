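import pytest
from hypothesis import HealthCheck, settings

from bptriage import (
    AbpmReading,
    AbpmSession,
    ClinicReading,
    ClinicVisit,
    Cohort,
    ConfusionTable,
    MeanBP,
    PatientRecord,
    Period,
    Sex,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_patient(
    pid="p1",
    clinic=((150, 95), (140, 90), (130, 85)),
    abpm_day=(138, 84),
    abpm_readings=None,
    **overrides,
):
    """A fully populated eligible patient, overridable per test."""
    visit = ClinicVisit(tuple(
        ClinicReading(s, d, order_index=i + 1)
        for i, (s, d) in enumerate(clinic)
    ))
    if abpm_readings is not None:
        session = AbpmSession(readings=tuple(
            AbpmReading(s, d, period=Period(p)) for s, d, p in abpm_readings
        ))
    elif abpm_day is not None:
        session = AbpmSession(daytime_mean=MeanBP(*abpm_day))
    else:
        session = AbpmSession()
    defaults = dict(
        age=55.0, sex=Sex.FEMALE, bmi=29.0, diabetes=False, ckd=False,
        af=False, cvd_history=False, hypertension_diagnosis=True,
        n_antihypertensives=1,
    )
    defaults.update(overrides)
    return PatientRecord(id=pid, visit=visit, abpm=session, **defaults)


@pytest.fixture
def overall_ct():
    """Confusion counts of the published validation cohort, overall."""
    return ConfusionTable(tp=584, tn=217, fp=69, fn=17)


@pytest.fixture
def small_cohort():
    return Cohort([
        make_patient("a", clinic=((150, 95), (148, 93), (146, 91)),
                     abpm_day=(142, 88)),
        make_patient("b", clinic=((128, 82), (126, 80), (124, 78)),
                     abpm_day=(122, 76)),
        make_patient("c", clinic=((140, 88), (138, 86), (136, 84)),
                     abpm_day=(131, 82)),
    ])
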