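# Methods

## Scope and model of the data

`lipidcv` implements a case-control plasma-lipidomics analysis for a
three-group HIV cardiovascular design: HIV-positive individuals sampled
before a first coronary event ("cases"), event-free HIV-positive
controls, and HIV-negative healthy controls. The measurement object is a
sample-by-species concentration matrix (316 species in 24 lipid classes
by default) with a species-to-class map, paired with a clinical
covariate table. Because such datasets are rarely shareable, the package
includes a first-class synthetic cohort generator whose injected effect
sizes provide ground truth for every estimator.

## Synthetic cohort generator

Log10 concentrations follow a one-factor-per-class Gaussian model

    z_ij = mu_j + delta_j(g_i) + sigma_j (l F_ic(j) + sqrt(1 - l^2) e_ij)

with a latent factor `F_ic` shared by all species of a class within a
sample and independent across classes and samples. The within-class
Pearson correlation of log concentrations is therefore `l^2` (default
loading `l = 0.6`, correlation 0.36), reflecting the coherent behaviour
of species within a lipid class; across classes the correlation is zero.
Concentrations are `10^z`, i.e. log-normal — positive and right-skewed,
the standard working assumption for lipidomics intensities. Defaults:
`mu = 2.0` (log10 pmol/mL, ~100 pmol/mL typical abundance) and
`sigma = 0.25` log10 units (~60% coefficient of variation, a realistic
biological spread for plasma lipids).

Covariates are drawn per group from Bernoulli (binary traits), normal or
log-normal (continuous traits) models parameterised by median and IQR,
with defaults emulating a treated-HIV case-control cohort: ~91% male,
median age ~51 y, heavy smoking/statin/family-history enrichment in the
HIV groups, low HDL and high triglycerides/hsCRP in cases. Traits that
exist at low frequency in any population (family history of CHD,
diabetes, statin use) are given small positive healthy-group rates
rather than exact zeros so that covariate-adjusted logistic fits remain
identifiable; an observed 0/45 draw is entirely compatible with these
rates. Healthy-control CD4 counts come from an HIV-negative reference
range (median 900 cells/µL). Covariates do not influence lipid values
unless explicit confounder links are configured (off by default), so the
association ground truth is exactly the injected group effects.

### Effect injection and OR-per-IQR calibration

Effects are specified as a target odds ratio per interquartile range
(OR per IQR) — the scale on which the association scan reports. For two
equal-variance Gaussian populations separated by `delta`, the population
logistic slope per unit is `delta / sigma^2`; equating it to
`ln(theta) / IQR` gives `delta = ln(theta) sigma^2 / IQR`
(`shift_from_target_or`). The IQR entering the scan, however, is
computed over the *pooled* two-group sample, and the shift itself widens
that pooled IQR. The generator therefore solves the fixed point
`delta = ln(theta) sigma^2 / IQR_mix(delta)`, where `IQR_mix` is the IQR
of the group-size-weighted two-component Gaussian mixture; without this
calibration the realized OR overshoots the target by ~17% at
`theta = 3.72`. With it, large-sample scans recover injected ORs to
within a few percent; small-cohort estimates still carry the usual
finite-sample logistic bias away from 1, which is a property of the
method, not of the generator.

Class-level effects shift every member species by a common log10 amount
sized from a delta-method approximation of the class-sum log SD
(weights proportional to expected concentrations, within-class
correlation `l^2`); the realized class OR is approximate by design and
tested with tolerance bands. Default injected effects are the
FDR-significant class-level associations this design is built to detect
(seven classes shifted with HIV infection, mostly sphingolipid and
plasmalogen depletion; eight glycerolipid/phospholipid classes elevated
ahead of cardiovascular events).

### What the generator does not emulate

No LC-MS batch effects, missingness, censoring, drift or
limit-of-detection artifacts; no covariate-lipid confounding by default;
species within a class are exchangeable (one factor, common loading)
rather than having the nested acyl-chain structure of real panels.
Passing tests therefore demonstrate correctness of the estimators under
a clean generative model, not robustness to real-data pathologies.

## Association scans

Each feature is analysed in its own binary logistic model — intercept,
feature, and the contrast's adjustment covariates (family history,
smoking and hsCRP for the HIV-infection contrast; current statin
treatment for the cardiovascular-event contrast). Fitting is
maximum-likelihood Newton/IRLS (statsmodels `Logit`), covariance from
the inverse observed information. Choices that matter:

* **Analysis scale**: species and class features are log10-transformed
  by default (configurable raw); the IQR that scales each odds ratio is
  computed on the same scale, over the samples entering that fit, by the
  inclusive linear-interpolation (type-7) quantile rule. The output
  records the IQR used, since OR-per-IQR is meaningless without it.
* **Class features** are per-sample sums of member-species
  concentrations, aggregated on the raw scale before transformation.
* **CIs** are 95% Wald intervals, `exp((beta ± 1.96 se) · IQR)`.
* **Multiplicity**: Benjamini-Hochberg step-up within each feature
  family — species and classes corrected separately within each
  contrast.
* **Degenerate fits**: constant features (zero IQR) are skipped with a
  warning; separated or non-converged fits keep their output row with a
  status flag and are excluded from the BH family rather than being
  given a fabricated CI. A binary adjustment covariate that
  quasi-separates the outcome (one of its level-by-outcome cells empty)
  would make *every* fit in the scan diverge, so it is dropped
  scan-wide, with a warning and a note in the result metadata.

Cohort characteristics are summarised as median (IQR) or % (x/n) and
compared by Mann-Whitney U tests (exact enumeration for tie-free pooled
samples of ≤ 12, tie-corrected normal approximation with continuity
correction otherwise) and two-sided Fisher's exact tests.

## Cross-validated risk prediction

The prediction task is discriminating HIV cases from HIV controls.
The harness is 3-fold class-stratified cross-validation: per repeat a
fresh stratified partition is drawn, each third serves once as the test
set, and the procedure is repeated 400 times — 1200 trials. Inside each
trial, using the training two-thirds only:

1. features are ranked by decreasing `|AUC - 0.5|` (two-sided univariate
   discrimination; an anti-correlated feature is as usable by a signed
   linear classifier as its mirror image), ties broken lexicographically;
2. the top `m` features are centred and scaled to unit SD with
   training-fold statistics;
3. a soft-margin linear SVM (`0.5 ||w||^2 + c Σ hinge`, default `c = 1`)
   is trained.

The held-out third is transformed with the training-fold parameters and
scored; AUC uses the continuous decision values (midrank formula, equal
to Mann-Whitney `U / n1 n0`), while accuracy, sensitivity, specificity,
PPV and NPV are computed at decision value 0 (the margin midpoint), with
zero-denominator ratios reported as missing rather than zero. Trial
metrics are aggregated as mean ± 1.96 SD/√n; feature stability is the
percentage of trials in which each feature was selected. The model size
`n*` is the smallest feature count maximising the mean AUC over a
1..max_features scan run with a common seed (all sizes see identical
partitions), optionally at reduced repeats.

A linear kernel with `c = 1` is the default because the data are tabular
with n ≪ p and a linear decision function keeps per-lipid weights
interpretable; both are configurable. "Conventional lipid" models use
the four clinical lipid covariates (HDL-C, LDL-C, total cholesterol,
triglycerides) on their native mmol/L scale; "combined" models append
them to the log10 species matrix.

### Null behaviour of the harness

Marginally — over independent cohorts — the held-out fold is independent
of everything the classifier saw, so the expected null test AUC is
exactly 0.5. Conditional on one finite cohort, however, the mean CV AUC
scatters widely (SD ≈ 0.06–0.08 for 68 samples): every trial reuses the
same samples, and in-training selection induces a train/test
anti-correlation within the cohort. Calibration checks therefore average
over many independent null cohorts (20 cohorts × 3 repeats in the test
suite) rather than deepening repeats on a single cohort, which would
converge to that cohort's conditional value, not to 0.5.

## Risk equations

Ten-year CHD risk comparators are evaluated declaratively: an equation
is a list of (variable, transform, coefficient) terms with optional
per-variable centering, mapped to absolute risk either through a Cox
baseline survival, `risk = 1 - S0^exp(L - L_ref)` (with `L_ref` the
cohort mean linear predictor), or through a Poisson-type rate,
`risk = 1 - exp(-exp(L) t)`. Antiretroviral-exposure terms of
D:A:D-style equations are years-of-exposure × per-year coefficient
identity terms. Published coefficient values are data, not code: the
shipped YAML templates carry the structural form with placeholder
coefficients and citation fields to be filled from the source
publications. Discrimination is the non-cross-validated C-statistic of
the computed risks against the outcome; samples with missing or invalid
covariates are excluded with a reported count.

## Reproducibility and numerics

One global seed expands into independent substreams (numpy
`SeedSequence` spawning) for lipid sampling, covariate sampling and each
CV repeat, so stages are independently reproducible and all outputs are
byte-identical under a fixed seed. Output tables carry a header comment
with tool version, config hash and seed. Percentages are reported to one
decimal and AUCs to three. SVM solving uses libsvm at tolerance 1e-6;
logistic fits use Newton iterations capped at 100 with parameter
tolerance 1e-8 and explicit rank-deficiency and separation checks.

## Problem sizes used in the checks

The test suite and acceptance script run the full design (113 × 316,
1200 trials) for the prediction harness; large-sample parameter recovery
uses 4000 samples per arm on a 3-species panel; null calibration uses 20
replicate cohorts; the model-size scan runs at 40 repeats per candidate
count. These sizes make the whole acceptance computation complete in
about a minute on a single core while keeping Monte-Carlo error well
inside the stated tolerance bands.

## Known limitations

Wald inference in small cohorts (23 vs 45) is anti-conservative for
large effects, and class-level ORs at that size can exceed their
injected targets noticeably; the separation-prone regime (quasi-complete
separation on strong class signals) is flagged rather than penalised
(no Firth correction). The generator's covariate models are marginal —
no age-smoking or BMI-lipid dependence. The CV harness does not nest the
model-size selection inside an outer validation loop, so `n*` inherits
the usual selection optimism; inclusion frequencies are reported as a
stability description, not as inference.
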