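# Template for a Framingham-style 10-year CHD risk equation.
#
# This file ships the structural form only. The published coefficient
# values and baseline survival are NOT included: copy this file, fill in
# the coefficients, baseline survival and centering values from the
# original publication you intend to use (record it in `citation`), and
# pass the edited file to `lipidcv risk --equation`.
name: framingham_chd_10y_template
form: cox_survival
terms:
  - {variable: age, transform: natural_log, coefficient: 0.0}
  - {variable: tc, transform: natural_log, coefficient: 0.0}
  - {variable: hdl, transform: natural_log, coefficient: 0.0}
  - {variable: sbp, transform: natural_log, coefficient: 0.0}
  - {variable: smoker, transform: binary, coefficient: 0.0}
  - {variable: diabetes, transform: binary, coefficient: 0.0}
# Baseline 10-year survival at the cohort reference predictor; replace
# with the published sex-specific value.
baseline_survival: 0.9
centering: {}
citation: "FILL IN: original Framingham CHD risk function publication"
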