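# bptriage

Tools for evaluating blood-pressure measurement strategies — in particular
model-based **triage for ambulatory blood pressure monitoring (ABPM)** —
against the daytime-ABPM reference standard.

## The problem

Daytime ABPM is the reference standard for diagnosing hypertension, but it is
resource-intensive. A triaging strategy applies a linear prediction model for
out-of-office BP to a patient's clinic readings (≥3 per visit) and electronic
health record covariates (age, sex, BMI, hypertension and treatment history,
cardiovascular disease), then splits patients three ways by the predicted BP
(S, D) against a referral band [L, U):

- **normotensive** if S < L_s and D < L_d,
- **hypertensive** if S ≥ U_s or D ≥ U_d,
- **refer for ABPM** otherwise.

Referred patients take their final class from ABPM itself; everyone is scored
against the daytime ABPM mean dichotomised at ≥135/85 mm Hg (either
component). Crossing the strategy's call with the reference yields the four
phenotypes: sustained hypertension (TP), normotension (TN), white-coat
hypertension (FP), masked hypertension (FN). From the resulting confusion
table the package computes sensitivity, specificity, predictive values,
correct-classification proportion, the binary-test AUROC
(= (Se + Sp)/2 for a dichotomous predictor), and ABPM utilisation, each with
Wald confidence intervals (Wilson and Clopper–Pearson optional), overall and
by subgroup.

A synthetic cohort generator (Gaussian latent ambulatory BP, subject-level
white-coat offsets, per-reading noise, first-reading elevation,
terminal-digit rounding) makes the whole pipeline testable without patient
data, and a 4-dimensional Gaussian integration gives the *expected* phenotype
mix in closed form as an independent oracle. See `docs/methods.md` for the
model details and limitations.

## Worked example

The published external validation of this triaging strategy (887 patients
referred for ABPM in UK primary and secondary care) reports the full
phenotype counts, so its headline statistics can be recomputed exactly:

```sh
bptriage report --tp 584 --tn 217 --fp 69 --fn 17 --referred 435 --name overall
```

prints

```
Population   N      AUROC (95% CI)         Sensitivity         Specificity                 PPV                 NPV             Correct            ABPM use
   overall 887 0.87 (0.84 to 0.89) 97.2 (95.8 to 98.5) 75.9 (70.9 to 80.8) 89.4 (87.1 to 91.8) 92.7 (89.4 to 96.1) 90.3 (88.4 to 92.3) 49.0 (45.8 to 52.3)
```

Reading: of the 601 truly hypertensive patients the strategy detected 97.2%
and of the 286 truly normotensive it ruled out 75.9%; 90.3% of all patients
were correctly classified while only 49% needed ABPM (uniform referral would
be 100%).

The same works end to end on files. Simulate a cohort, triage it, and
evaluate the strategy against the simulated ABPM:

```sh
bptriage simulate --seed 3 --n 500 --out cohort.csv --truth truth.csv
bptriage triage cohort.csv --out decisions.csv     # id, predicted BP, decision
bptriage evaluate cohort.csv --subgroups --out metrics.json
```

`decisions.csv` starts like

```
id,predicted_sbp,predicted_dbp,decision
sim001,107.63,47.21,normotensive
sim002,130.05,80.98,refer_abpm
```

and `metrics.json` carries the confusion table, all accuracy metrics with
CIs, utilisation, and per-subgroup reports. Without `--config` the commands
use the shipped *illustrative* coefficient set
(`src/bptriage/data/illustrative_model.yaml`); to run a published model,
transcribe its coefficients and referral band into a copy of that file.

From Python the same pipeline is:

```python
from bptriage import *
from bptriage.datasets import illustrative_model_config

cohort, truth = simulate_cohort(SimulationParams(n=500, seed=3))
cfg = illustrative_model_config()
spec = StrategySpec(kind="proofbp_triage",
                    coefficients=cfg.coefficients, bands=cfg.bands)
cls, dropped = apply_strategy(cohort, spec)
print(accuracy_report(confusion_of(cls),
                      n_referred=sum(c.used_abpm for c in cls)).to_dict())
```

## Layout

| Module | Role |
| --- | --- |
| `bptriage.cohort` | domain types, CSV I/O (wide/long dialects), eligibility filters |
| `bptriage.reference` | ABPM summaries, threshold status, phenotype mapping |
| `bptriage.model` | linear out-of-office BP prediction, three-way triage rule |
| `bptriage.strategy` | strategy application, referral resolution, confusion tables |
| `bptriage.stats` | accuracy metrics, Wald/Wilson/Clopper–Pearson CIs, binary AUROC, subgroups |
| `bptriage.simulate` | synthetic cohort generator and analytic prevalence oracle |
| `bptriage.datasets` | published validation counts, patient-level reconstruction |
| `bptriage.cli` | `simulate` / `validate` / `triage` / `evaluate` / `report` subcommands |
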