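# Template for a D:A:D-style HIV-specific 10-year CHD risk equation.
#
# Rate (Poisson) form: risk = 1 - exp(-exp(L) * horizon_years). The
# antiretroviral-exposure terms are expressed as years-of-exposure times
# a per-year coefficient (identity transform). Structural form only:
# fill in published coefficients from the source publication (record it
# in `citation`) before use. Variables ending in `_years` are expected
# as additional columns in the sample metadata.
name: dad_chd_10y_template
form: log_rate
terms:
  - {variable: age, transform: identity, coefficient: 0.0}
  - {variable: male, transform: binary, coefficient: 0.0}
  - {variable: sbp, transform: identity, coefficient: 0.0}
  - {variable: tc, transform: identity, coefficient: 0.0}
  - {variable: hdl, transform: identity, coefficient: 0.0}
  - {variable: smoker, transform: binary, coefficient: 0.0}
  - {variable: diabetes, transform: binary, coefficient: 0.0}
  - {variable: family_history_chd, transform: binary, coefficient: 0.0}
  # per-year antiretroviral exposure terms
  - {variable: pi_exposure_years, transform: identity, coefficient: 0.0}
  - {variable: nrti_exposure_years, transform: identity, coefficient: 0.0}
horizon_years: 10.0
centering: {}
citation: "FILL IN: original D:A:D CHD risk equation publication"
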