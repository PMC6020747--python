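"""Synthetic cohort generation with a controllable clinic-ambulatory joint
BP distribution.

The generative model is Gaussian throughout.  Each patient has a latent
daytime ambulatory mean BP drawn from a bivariate normal (systolic,
diastolic).  ABPM readings scatter around the latent mean with within-subject
reading noise; night readings scatter around a dipped copy of it.  Clinic
readings equal the latent ambulatory mean plus a subject-level white-coat
offset, per-reading noise, an optional first-reading elevation, and an
optional terminal-digit rounding artifact emulating routine-practice
recording.  Covariates are drawn from configurable marginals.

Defaults are calibrated so the simulated marginals approximate a routine
referral population (clinic ~147/91 mm Hg with SD ~19/13, daytime ABPM
~141/83, ~70% with diagnosed hypertension); the white-coat offset mean and
SD are solved from those targets given the reading noise and visit length.

Because every component is Gaussian, the joint distribution of the observed
clinic visit mean and observed daytime ABPM mean is Gaussian too, so the
expected phenotype mix has a closed form up to a 4-dimensional normal
orthant probability — :func:`phenotype_prevalence` evaluates it by numeric
integration and serves as the independent oracle for end-to-end pipeline
tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .cohort import (
    AbpmReading,
    AbpmSession,
    ClinicReading,
    ClinicVisit,
    Cohort,
    PatientRecord,
    Setting,
    Sex,
    Smoking,
)
from .exceptions import UnsupportedAnalyticError
from .reference import BPThreshold, MeanBP, Period, Phenotype, bp_status, phenotype_of

__all__ = [
    "RoundingRule",
    "CovariateMarginals",
    "SimulationParams",
    "TrueState",
    "simulate_cohort",
    "phenotype_prevalence",
    "truth_to_frame",
]

_DEFAULT_THRESHOLD = BPThreshold(135.0, 85.0)


@dataclass(frozen=True, slots=True)
class RoundingRule:
    """Recording artifact applied to clinic readings.

    ``none`` leaves readings exact; ``nearest_2`` emulates 2-mm Hg device
    granularity; ``terminal_zero`` emulates terminal-digit bias (rounding to
    the nearest 10).  ``probability`` is the per-reading chance the artifact
    applies.
    """

    kind: str = "none"  # none | nearest_2 | terminal_zero
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "nearest_2", "terminal_zero"):
            raise ValueError(f"unknown rounding kind {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")

    @property
    def modulus(self) -> float:
        return {"none": 0.0, "nearest_2": 2.0, "terminal_zero": 10.0}[self.kind]


@dataclass(frozen=True, slots=True)
class CovariateMarginals:
    """Marginal covariate distributions for the generator (defaults match a
    routine hypertension-referral population)."""

    age_mean: float = 52.8
    age_sd: float = 16.2
    female_prop: float = 0.538
    bmi_mean: float = 30.8
    bmi_sd: float = 8.1
    smoking_probs: tuple[float, float, float, float] = (0.140, 0.231, 0.563, 0.066)
    diabetes_prop: float = 0.131
    ckd_prop: float = 0.067
    af_prop: float = 0.033
    cvd_prop: float = 0.130
    hypertension_diagnosis_prop: float = 0.698
    #: distribution of antihypertensive drug count 0..4+ (unconditional);
    #: treatment is drawn conditional on a hypertension diagnosis.
    n_antihypertensives_probs: tuple[float, ...] = (0.394, 0.245, 0.168, 0.115, 0.078)
    primary_care_prop: float = 0.399

    def __post_init__(self) -> None:
        for name in ("female_prop", "diabetes_prop", "ckd_prop", "af_prop",
                     "cvd_prop", "hypertension_diagnosis_prop",
                     "primary_care_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-6:
            raise ValueError("smoking_probs must sum to 1")
        if abs(sum(self.n_antihypertensives_probs) - 1.0) > 1e-6:
            raise ValueError("n_antihypertensives_probs must sum to 1")
        treated = sum(self.n_antihypertensives_probs[1:])
        if treated > self.hypertension_diagnosis_prop + 1e-9:
            raise ValueError("treated share cannot exceed diagnosed share")


def _default_white_coat_mean() -> tuple[float, float]:
    # solve clinic target 146.7/90.6 = ambulatory + offset + elevation/K
    return (146.7 - 140.8 - 5.0 / 3, 90.6 - 83.4 - 3.0 / 3)


def _default_white_coat_sd() -> tuple[float, float]:
    # solve clinic-mean SD target 19.2/12.5 given ambulatory SD and
    # within-visit noise averaged over K=3 readings
    return (
        math.sqrt(19.2 ** 2 - 16.8 ** 2 - 8.0 ** 2 / 3),
        math.sqrt(12.5 ** 2 - 11.7 ** 2 - 6.0 ** 2 / 3),
    )


@dataclass(frozen=True, slots=True)
class SimulationParams:
    """Generative settings for one synthetic cohort.

    All BP quantities are mm Hg; two-element tuples are (systolic,
    diastolic).
    """

    n: int = 887
    seed: int = 0
    ambulatory_mean: MeanBP = MeanBP(140.8, 83.4)
    ambulatory_sd: tuple[float, float] = (16.8, 11.7)
    #: between-subject systolic-diastolic correlation of latent ambulatory
    #: means (placeholder value; the real correlation is unpublished)
    sd_correlation: float = 0.7
    white_coat_mean: tuple[float, float] = field(
        default_factory=_default_white_coat_mean)
    white_coat_sd: tuple[float, float] = field(
        default_factory=_default_white_coat_sd)
    reading_noise_sd: tuple[float, float] = (8.0, 6.0)
    first_reading_elevation: tuple[float, float] = (5.0, 3.0)
    n_clinic_readings: int = 3
    n_abpm_day: int = 28
    n_abpm_night: int = 14
    abpm_reading_sd: tuple[float, float] = (12.0, 8.0)
    #: fractional day-to-night BP drop (calibrated to typical night/day
    #: summary ratios)
    nocturnal_dip: tuple[float, float] = (0.087, 0.113)
    rounding: RoundingRule = field(default_factory=RoundingRule)
    covariate_marginals: CovariateMarginals = field(
        default_factory=CovariateMarginals)
    #: store raw ABPM readings (True) or only their period means (False);
    #: downstream summaries are identical, summaries-only is lighter at
    #: large n
    keep_raw_abpm: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_clinic_readings < 3:
            raise ValueError("n_clinic_readings must be >= 3")
        if self.n_abpm_day < 1:
            raise ValueError("n_abpm_day must be >= 1")
        if self.n_abpm_night < 0:
            raise ValueError("n_abpm_night must be >= 0")
        if not -1.0 <= self.sd_correlation <= 1.0:
            raise ValueError("sd_correlation must be in [-1, 1]")
        for name in ("ambulatory_sd", "white_coat_sd", "reading_noise_sd",
                     "abpm_reading_sd"):
            pair = getattr(self, name)
            if min(pair) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not all(0.0 <= f < 1.0 for f in self.nocturnal_dip):
            raise ValueError("nocturnal_dip fractions must be in [0, 1)")


@dataclass(frozen=True, slots=True)
class TrueState:
    """Per-patient generator ground truth for oracle checks.

    ``phenotype`` is defined from the noise-free means (latent ambulatory
    mean vs the expected clinic mean), so it is exact rather than a noisy
    realisation.
    """

    id: str
    latent_day: MeanBP
    latent_night: MeanBP
    clinic_true_mean: MeanBP
    phenotype: Phenotype


def truth_to_frame(states: list[TrueState]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "id": s.id,
            "latent_day_sbp": s.latent_day.systolic,
            "latent_day_dbp": s.latent_day.diastolic,
            "latent_night_sbp": s.latent_night.systolic,
            "latent_night_dbp": s.latent_night.diastolic,
            "clinic_true_sbp": s.clinic_true_mean.systolic,
            "clinic_true_dbp": s.clinic_true_mean.diastolic,
            "phenotype": s.phenotype.value,
        }
        for s in states
    ])


def _physiologic(s: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp rare Gaussian-tail draws to satisfy systolic > diastolic > 0."""
    s = np.maximum(s, 2.0)
    d = np.clip(d, 1.0, s - 1.0)
    return s, d


def _apply_rounding(values: np.ndarray, rule: RoundingRule,
                    rng: np.random.Generator) -> np.ndarray:
    if rule.kind == "none" or rule.probability == 0.0:
        return values
    m = rule.modulus
    rounded = np.round(values / m) * m
    mask = rng.random(values.shape) < rule.probability
    return np.where(mask, rounded, values)


def _latent_cov(params: SimulationParams) -> np.ndarray:
    ss, sd = params.ambulatory_sd
    c = params.sd_correlation * ss * sd
    return np.array([[ss ** 2, c], [c, sd ** 2]])


def simulate_cohort(params: SimulationParams) -> tuple[Cohort, list[TrueState]]:
    """Draw a synthetic cohort; deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n, K = params.n, params.n_clinic_readings
    cm = params.covariate_marginals

    mu = np.array([params.ambulatory_mean.systolic,
                   params.ambulatory_mean.diastolic])
    latent = rng.multivariate_normal(mu, _latent_cov(params), size=n)
    wc = rng.normal(params.white_coat_mean, params.white_coat_sd, size=(n, 2))
    elev = np.asarray(params.first_reading_elevation)

    # clinic readings: (n, K, 2)
    noise = rng.normal(0.0, params.reading_noise_sd, size=(n, K, 2))
    clinic = latent[:, None, :] + wc[:, None, :] + noise
    clinic[:, 0, :] += elev
    clinic_s = _apply_rounding(clinic[..., 0], params.rounding, rng)
    clinic_d = _apply_rounding(clinic[..., 1], params.rounding, rng)
    clinic_s, clinic_d = _physiologic(clinic_s, clinic_d)

    # ABPM readings around the latent means (day) / dipped means (night)
    dip = np.array([1 - params.nocturnal_dip[0], 1 - params.nocturnal_dip[1]])
    night_latent = latent * dip
    day = latent[:, None, :] + rng.normal(
        0.0, params.abpm_reading_sd, size=(n, params.n_abpm_day, 2))
    day_s, day_d = _physiologic(day[..., 0], day[..., 1])
    if params.n_abpm_night > 0:
        night = night_latent[:, None, :] + rng.normal(
            0.0, params.abpm_reading_sd, size=(n, params.n_abpm_night, 2))
        night_s, night_d = _physiologic(night[..., 0], night[..., 1])
    else:
        night_s = night_d = np.empty((n, 0))

    # covariates
    age = np.maximum(rng.normal(cm.age_mean, cm.age_sd, n), 18.0)
    female = rng.random(n) < cm.female_prop
    bmi = np.maximum(rng.normal(cm.bmi_mean, cm.bmi_sd, n), 12.0)
    smoking_codes = rng.choice(4, size=n, p=cm.smoking_probs)
    smoking_levels = (Smoking.CURRENT, Smoking.FORMER, Smoking.NEVER,
                      Smoking.UNKNOWN)
    diabetes = rng.random(n) < cm.diabetes_prop
    ckd = rng.random(n) < cm.ckd_prop
    af = rng.random(n) < cm.af_prop
    cvd = rng.random(n) < cm.cvd_prop
    dx = rng.random(n) < cm.hypertension_diagnosis_prop
    # drug count conditional on diagnosis: untreated patients without a
    # diagnosis take 0 drugs; conditional probabilities rescale the
    # unconditional count distribution by the diagnosed share
    p = np.asarray(cm.n_antihypertensives_probs)
    p_dx = cm.hypertension_diagnosis_prop
    if p_dx > 0:
        cond = np.concatenate(([1 - p[1:].sum() / p_dx], p[1:] / p_dx))
        cond = np.clip(cond, 0, None)
        cond = cond / cond.sum()
    else:
        cond = np.array([1.0] + [0.0] * (len(p) - 1))
    n_drugs = np.where(dx, rng.choice(len(cond), size=n, p=cond), 0)
    primary = rng.random(n) < cm.primary_care_prop

    thr = _DEFAULT_THRESHOLD
    clinic_true = latent + wc + elev / K
    lat_s, lat_d = _physiologic(latent[:, 0], latent[:, 1])
    nlat_s, nlat_d = _physiologic(night_latent[:, 0], night_latent[:, 1])
    ct_s, ct_d = _physiologic(clinic_true[:, 0], clinic_true[:, 1])

    patients: list[PatientRecord] = []
    states: list[TrueState] = []
    width = len(str(n))
    for i in range(n):
        readings = tuple(
            ClinicReading(float(clinic_s[i, j]), float(clinic_d[i, j]),
                          order_index=j + 1)
            for j in range(K)
        )
        if params.keep_raw_abpm:
            abpm = tuple(
                AbpmReading(float(day_s[i, j]), float(day_d[i, j]), Period.DAY)
                for j in range(params.n_abpm_day)
            ) + tuple(
                AbpmReading(float(night_s[i, j]), float(night_d[i, j]),
                            Period.NIGHT)
                for j in range(params.n_abpm_night)
            )
            session = AbpmSession(readings=abpm)
        else:
            all_s = np.concatenate([day_s[i], night_s[i]])
            all_d = np.concatenate([day_d[i], night_d[i]])
            session = AbpmSession(
                daytime_mean=MeanBP(float(day_s[i].mean()), float(day_d[i].mean())),
                night_mean=(MeanBP(float(night_s[i].mean()),
                                   float(night_d[i].mean()))
                            if params.n_abpm_night > 0 else None),
                h24_mean=MeanBP(float(all_s.mean()), float(all_d.mean())),
            )
        pid = f"sim{i + 1:0{width}d}"
        patients.append(PatientRecord(
            id=pid,
            visit=ClinicVisit(readings),
            abpm=session,
            age=float(age[i]),
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            bmi=float(bmi[i]),
            smoking=smoking_levels[smoking_codes[i]],
            diabetes=bool(diabetes[i]),
            ckd=bool(ckd[i]),
            af=bool(af[i]),
            cvd_history=bool(cvd[i]),
            hypertension_diagnosis=bool(dx[i]),
            n_antihypertensives=int(n_drugs[i]),
            setting=Setting.PRIMARY if primary[i] else Setting.SECONDARY,
        ))
        latent_day = MeanBP(float(lat_s[i]), float(lat_d[i]))
        ct_mean = MeanBP(float(ct_s[i]), float(ct_d[i]))
        states.append(TrueState(
            id=pid,
            latent_day=latent_day,
            latent_night=MeanBP(float(nlat_s[i]), float(nlat_d[i])),
            clinic_true_mean=ct_mean,
            phenotype=phenotype_of(bp_status(ct_mean, thr),
                                   bp_status(latent_day, thr)),
        ))
    cohort = Cohort(patients, provenance=f"simulated(seed={params.seed}, n={n})")
    return cohort, states


def _observed_joint(params: SimulationParams,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of (clinic mean S, clinic mean D, ABPM day mean S,
    ABPM day mean D) under the Gaussian generator."""
    K, m = params.n_clinic_readings, params.n_abpm_day
    Sig = _latent_cov(params)
    mu = np.array([params.ambulatory_mean.systolic,
                   params.ambulatory_mean.diastolic])
    wc_mu = np.asarray(params.white_coat_mean)
    elev = np.asarray(params.first_reading_elevation)
    wc_var = np.asarray(params.white_coat_sd) ** 2
    noise_var = np.asarray(params.reading_noise_sd) ** 2 / K
    abpm_var = np.asarray(params.abpm_reading_sd) ** 2 / m

    mean4 = np.concatenate([mu + wc_mu + elev / K, mu])
    cov4 = np.zeros((4, 4))
    cov4[:2, :2] = Sig + np.diag(wc_var + noise_var)
    cov4[2:, 2:] = Sig + np.diag(abpm_var)
    cov4[:2, 2:] = Sig
    cov4[2:, :2] = Sig
    return mean4, cov4


def phenotype_prevalence(
    params: SimulationParams,
    threshold_clinic: BPThreshold = _DEFAULT_THRESHOLD,
    threshold_abpm: BPThreshold = _DEFAULT_THRESHOLD,
    method: str = "analytic",
    mc_n: int = 1_000_000,
    mc_seed: int | None = None,
) -> dict[Phenotype, float]:
    """Expected phenotype proportions for the observed clinic visit mean
    cross-classified against the observed daytime ABPM mean.

    ``analytic`` integrates the 4-dimensional Gaussian (requires the fully
    Gaussian configuration, i.e. no rounding artifact); ``monte_carlo`` is
    the sampling fallback that also covers rounding.
    """
    if method == "analytic":
        if params.rounding.kind != "none" and params.rounding.probability > 0:
            raise UnsupportedAnalyticError(
                "rounding artifact breaks the Gaussian assumption; "
                "use method='monte_carlo'"
            )
        mean4, cov4 = _observed_joint(params)
        t = np.array([threshold_clinic.systolic, threshold_clinic.diastolic,
                      threshold_abpm.systolic, threshold_abpm.diastolic])
        # allow_singular covers degenerate (noise-free) configurations where
        # the clinic and ambulatory means coincide
        p_nn = float(multivariate_normal(
            mean4, cov4, allow_singular=True).cdf(t))
        p_clinic_norm = float(multivariate_normal(
            mean4[:2], cov4[:2, :2], allow_singular=True).cdf(t[:2]))
        p_abpm_norm = float(multivariate_normal(
            mean4[2:], cov4[2:, 2:], allow_singular=True).cdf(t[2:]))
        return {
            Phenotype.SUSTAINED_HYPERTENSION:
                1.0 - p_clinic_norm - p_abpm_norm + p_nn,
            Phenotype.WHITE_COAT_HYPERTENSION: p_abpm_norm - p_nn,
            Phenotype.MASKED_HYPERTENSION: p_clinic_norm - p_nn,
            Phenotype.NORMOTENSION: p_nn,
        }
    if method == "monte_carlo":
        rng = np.random.default_rng(
            params.seed if mc_seed is None else mc_seed)
        K, m = params.n_clinic_readings, params.n_abpm_day
        mu = np.array([params.ambulatory_mean.systolic,
                       params.ambulatory_mean.diastolic])
        latent = rng.multivariate_normal(mu, _latent_cov(params), size=mc_n)
        noise = rng.normal(0.0, params.reading_noise_sd, size=(mc_n, K, 2))
        clinic = (latent[:, None, :]
                  + rng.normal(params.white_coat_mean, params.white_coat_sd,
                               size=(mc_n, 2))[:, None, :]
                  + noise)
        clinic[:, 0, :] += np.asarray(params.first_reading_elevation)
        cs = _apply_rounding(clinic[..., 0], params.rounding, rng).mean(axis=1)
        cd = _apply_rounding(clinic[..., 1], params.rounding, rng).mean(axis=1)
        obs = latent + rng.normal(
            0.0, np.asarray(params.abpm_reading_sd) / math.sqrt(m),
            size=(mc_n, 2))
        clinic_hyper = ((cs >= threshold_clinic.systolic)
                        | (cd >= threshold_clinic.diastolic))
        abpm_hyper = ((obs[:, 0] >= threshold_abpm.systolic)
                      | (obs[:, 1] >= threshold_abpm.diastolic))
        return {
            Phenotype.SUSTAINED_HYPERTENSION:
                float((clinic_hyper & abpm_hyper).mean()),
            Phenotype.WHITE_COAT_HYPERTENSION:
                float((clinic_hyper & ~abpm_hyper).mean()),
            Phenotype.MASKED_HYPERTENSION:
                float((~clinic_hyper & abpm_hyper).mean()),
            Phenotype.NORMOTENSION:
                float((~clinic_hyper & ~abpm_hyper).mean()),
        }
    raise ValueError(f"unknown method {method!r}")
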