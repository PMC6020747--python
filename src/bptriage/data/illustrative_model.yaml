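# Illustrative out-of-office BP prediction model and triage band.
#
# These coefficient values are NOT the published triage model's: they are an
# illustrative set with the published model's structure (clinic-mean anchor
# plus small covariate adjustments), shipped so the pipeline runs end to end.
# To reproduce a published strategy, transcribe its coefficients and referral
# band from the original publication's supplement into a copy of this file.
model:
  coefficients:
    name: illustrative-v1
    intercept_systolic: 8.0
    intercept_diastolic: 4.0
    terms:
      - covariate: clinic_sbp_mean
        beta_systolic: 0.85
        beta_diastolic: 0.0
      - covariate: clinic_dbp_mean
        beta_systolic: 0.0
        beta_diastolic: 0.85
      - covariate: age
        transform: "center:50"
        beta_systolic: 0.10
        beta_diastolic: -0.02
      - covariate: bmi
        transform: "center:30"
        beta_systolic: 0.05
        beta_diastolic: 0.05
      - covariate: sex_male
        beta_systolic: 1.0
        beta_diastolic: 0.5
      - covariate: hypertension_diagnosis
        beta_systolic: 1.5
        beta_diastolic: 1.0
      - covariate: treated
        beta_systolic: -1.0
        beta_diastolic: -0.5
      - covariate: cvd_history
        beta_systolic: 0.5
        beta_diastolic: 0.0
  bands:
    lower: {systolic: 130, diastolic: 80}
    upper: {systolic: 145, diastolic: 90}
  mean_rule: all
reference:
  day: {systolic: 135, diastolic: 85}
  night: {systolic: 120, diastolic: 70}
  h24: {systolic: 130, diastolic: 80}
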