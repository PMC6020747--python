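# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was open, and what the synthetic-data tests do
and do not establish about real cohorts.

## Triage model and strategy scoring

The out-of-office prediction model is a pair of linear equations,

    S_pred = a_S + Σ_j b_Sj · t_j(x_j),   D_pred = a_D + Σ_j b_Dj · t_j(x_j),

over clinic-BP-derived regressors (visit mean, last reading, within-visit
range) and patient covariates (age, sex, BMI, hypertension diagnosis,
treatment, cardiovascular disease), with a small transform grammar
(`identity`, `center:c`, `scale:c`, `square`, `log`). Coefficients and the
referral band are configuration data, not code; the shipped set is
illustrative and is labelled as such in the config file. The identity model
(prediction = clinic visit mean, `identity_coefficients()`) is a useful
baseline and makes the triage rule collapse to a fixed clinic threshold when
the band is collapsed.

The three-way rule is: hypertensive if either predicted component is at or
above the upper band bound, normotensive if both are strictly below the lower
bound, referred otherwise. The OR (upper) / AND (lower) composition is the
only one that keeps the three groups exhaustive and mutually exclusive; it
also makes the decision monotone in each predicted component, which the
property tests assert.

Scoring convention: referred patients take their final class from the
reference-standard ABPM itself, so they can only score as sustained
hypertension or normotension — false positives (white-coat) and false
negatives (masked hypertension) arise exclusively among patients classified
without ABPM. Consequently widening the band can only shift errors into the
referred (error-free) group: utilisation weakly rises, FP+FN weakly falls.

All thresholds use the either-component rule with inclusive ≥: a mean is
hypertensive when systolic ≥ T_s **or** diastolic ≥ T_d. Defaults: daytime
135/85 mm Hg (the reference standard), night 120/70, 24 h 130/80 — the
conventional guideline values, configurable under `reference.*` in the YAML
config.

## Eligibility

Retained patients have ≥3 clinic readings from one visit, age ≥18, every
covariate the configured prediction model needs, and usable daytime ABPM.
Each excluded patient receives exactly one primary reason, assigned in the
fixed precedence order *missing BP → under 18 → missing clinical information
→ ABPM not worn*, so exclusion counts are disjoint. Requiredness of a
covariate is model-driven: BMI excludes only because the default model uses
it; smoking and other covariates the model ignores never exclude. A missing
age falls under missing clinical information (it cannot prove adulthood
either way).

## Confidence intervals

Binomial proportions use the Wald normal approximation
`p ± z·sqrt(p(1−p)/n)` with bounds clipped to [0, 1]. Wald was chosen
because it uniquely reproduces the intervals printed in the validation study
(e.g. 95.8–98.5 for 584/601, where Wilson gives 95.5–98.2); Wilson and
Clopper–Pearson remain available via `method=`. Wald is known to undercover
for small n or extreme p — at the cohort sizes involved here (hundreds) the
approximation is adequate, but small subgroup strata should prefer Wilson.

For a dichotomous test the ROC curve has a single interior operating point
and AUROC = (Se + Sp)/2 exactly; the property tests verify this against the
empirical rank (Mann–Whitney) AUROC on expanded 0/1 labels. Its standard
error is taken as `SE = ½·sqrt(SE_Se² + SE_Sp²)` (independent binomial
sampling within the diseased and non-diseased groups), which reproduces the
printed AUROC intervals; a delta-method CI from the equivalent logistic
model would be asymptotically similar but is not implemented. Metrics with
empty denominators are reported as missing, never as 0 or 1. Subgroup
results are descriptive; no multiplicity adjustment is applied.

## Synthetic cohort generator

Per patient, with all BP pairs (systolic, diastolic) in mm Hg:

1. latent daytime ambulatory mean `L ~ N₂(μ, Σ)` with defaults
   μ = (140.8, 83.4), SD (16.8, 11.7) and correlation 0.7 (the real
   clinic–ambulatory S–D correlation is unpublished; 0.7 is a documented
   placeholder);
2. ABPM readings: `n_abpm_day` (default 28) draws around `L` and
   `n_abpm_night` (default 14) around the dipped mean
   `L·(1−dip)`, dip = (0.087, 0.113), with within-subject reading SD
   (12, 8) — a parameter the generator needs even though only summary means
   are usually reported;
3. subject white-coat offset `W ~ N(w, τ²)` applied to all clinic readings;
4. clinic readings: `L + W + ε_j` with per-reading noise SD (8, 6), plus a
   first-reading elevation (5, 3) on reading 1, then the optional rounding
   artifact (`nearest_2` or `terminal_zero`, per-reading probability).

Calibration: the white-coat offset mean `w` is solved so the expected clinic
visit mean hits (146.7, 90.6) given the elevation spread over K = 3
readings, and its SD `τ` so the between-patient SD of the clinic visit mean
hits (19.2, 12.5) given Σ and the averaged reading noise — i.e. the
defaults *are* the target marginals of a routine referral population, not
fitted quantities. The nocturnal dip is calibrated the same way from the
night/day summary ratios rather than set to a flat 10%. Covariates are drawn
from marginals matching that population (age 52.8 ± 16.2, 53.8% female, BMI
30.8 ± 8.1, 69.8% diagnosed hypertensive, drug counts conditional on
diagnosis so only diagnosed patients are treated).

Gaussian-tail draws violating systolic > diastolic > 0 (probability ~10⁻³
per reading at the defaults) are clamped to the boundary; the effect on any
tested quantity is far below Monte-Carlo resolution but means the generator
is not *exactly* the unbounded Gaussian the oracle integrates.

Ground truth (`TrueState`) records the latent means and the phenotype
implied by the noise-free clinic mean `L + W + elevation/K` versus `L`, so
oracle checks against the truth are exact rather than noisy.

### Analytic prevalence oracle

With every component Gaussian, the observed clinic visit mean `C` and
observed daytime ABPM mean `O` are jointly normal in four dimensions with

    E[C] = μ + w + e/K,  E[O] = μ,
    Cov(C) = Σ + diag(τ² + σ²_read/K),  Cov(O) = Σ + diag(σ²_abpm/m),
    Cov(C, O) = Σ.

The four phenotype probabilities are inclusion–exclusion combinations of the
2- and 4-dimensional normal CDFs at the thresholds, evaluated with scipy's
multivariate-normal CDF (`allow_singular` covers noise-free degenerate
configurations). The rounding artifact breaks normality, so the analytic
route refuses it and a vectorised Monte-Carlo fallback covers that case.
The end-to-end test generates 100 000 patients, classifies them with the
direct fixed-threshold strategy (the collapsed-band limit of the triage
rule), and requires each observed phenotype share to fall within 3
binomial SEs of the integral. Note the OR rule makes "sustained vs
normotension symmetry" hold only when a single component drives the
classification; the symmetric-configuration test is constructed accordingly.

## What the synthetic tests do not show

The generator emulates the *marginal and joint second-moment structure* of a
referral cohort plus simple measurement artifacts. It does not model:
covariate–BP dependence (age, treatment and BMI are independent of BP in the
generator, so simulated subgroup analyses exercise the machinery, not
epidemiology); visit-to-visit variability or regression to the mean;
heavy-tailed or skewed BP distributions; device error structure; or informed
presence (who gets referred). Passing tests therefore validate the pipeline
arithmetic and the stated distributional logic — not the clinical
performance of any particular coefficient set, which must come from external
validation data.

## Problem sizes and numerical choices

Unit tests run cohorts of 60–800 patients; calibration checks use 10 000
(marginals within 1 mm Hg) and 50 000 (latent moments within 2%); the
end-to-end oracle comparison uses 100 000 patients with summary-only ABPM
storage. Floating-point identities are asserted to 1e-9 (means) or 1e-12
(algebraic identities); the multivariate CDF is accurate to ~1e-6, so
analytic-vs-MC assertions use 3 SE bounds. Seeds are fixed everywhere; a
fixed seed reproduces cohorts byte-identically through the CSV writer.

## Known limitations

- The shipped coefficient set is illustrative; no published coefficients are
  bundled, and the package deliberately does not re-derive (fit) them.
- The guideline-comparator presets are a generic
  "clinic ≥ T → confirm with ABPM (or diagnose directly)" pattern, not exact
  transcriptions of any national guideline.
- Wald intervals (the default for comparability with the validation study)
  are anti-conservative in small strata.
- The Table-style integer display of one utilisation CI in the source study
  (55 for 165/268) is not reproducible with any rounding of the Wald bound
  (55.7); the package reports its own computed value.
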