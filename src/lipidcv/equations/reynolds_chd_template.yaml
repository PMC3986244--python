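# Template for a Reynolds-style 10-year CHD risk equation (adds hsCRP
# and family history to the traditional risk factors).
#
# Structural form only: fill in published coefficients, baseline
# survival and centering from the source publication (record it in
# `citation`) before use.
name: reynolds_chd_10y_template
form: cox_survival
terms:
  - {variable: age, transform: identity, coefficient: 0.0}
  - {variable: sbp, transform: natural_log, coefficient: 0.0}
  - {variable: hscrp, transform: natural_log, coefficient: 0.0}
  - {variable: tc, transform: natural_log, coefficient: 0.0}
  - {variable: hdl, transform: natural_log, coefficient: 0.0}
  - {variable: smoker, transform: binary, coefficient: 0.0}
  - {variable: family_history_chd, transform: binary, coefficient: 0.0}
baseline_survival: 0.98
centering: {}
citation: "FILL IN: original Reynolds risk score publication"
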