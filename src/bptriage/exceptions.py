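"""Exception hierarchy for bptriage."""


class BPTriageError(Exception):
    """Base class for all bptriage errors."""


class CohortSchemaError(BPTriageError):
    """A mandatory column is absent or the schema config is unusable."""


class MissingPeriodError(BPTriageError):
    """An ABPM summary was requested for a period with no readings or summary."""


class InsufficientReadingsError(BPTriageError):
    """A clinic visit has too few readings for the requested averaging rule."""


class MissingCovariateError(BPTriageError):
    """A covariate required by the prediction model is absent for a patient."""

    def __init__(self, covariate: str, patient_id: str | None = None):
        self.covariate = covariate
        self.patient_id = patient_id
        where = f" for patient {patient_id!r}" if patient_id is not None else ""
        super().__init__(f"missing required covariate {covariate!r}{where}")


class ModelConfigError(BPTriageError):
    """A coefficient set, transform, or triage band configuration is invalid."""


class UndefinedMetricError(BPTriageError):
    """An accuracy metric has a zero denominator and is undefined."""


class UnsupportedAnalyticError(BPTriageError):
    """Analytic prevalence requested for a non-Gaussian generator configuration."""
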