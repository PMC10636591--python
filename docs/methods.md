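# Methods

## The survival model

All scenario models are flexible parametric proportional-hazards models on
the log-cumulative-hazard scale: η(t|x) = s(ln t; γ) + x'β, with restricted
cubic splines for the baseline `s` and, where selected, for covariate
transforms and time-dependent effects (covariate × log-time spline blocks).
The likelihood is the exact censored-data likelihood
Σ dᵢ[ln(∂ηᵢ/∂ln t) − ln tᵢ + ηᵢ] − exp(ηᵢ); subjects whose fitted
∂η/∂ln t is non-positive at an event time contribute −∞, which is reported
rather than clipped. The timescale is time since cohort entry, with entry at
0 for everyone (no delayed entry / left truncation).

Numerical choices:

- **Splines.** Restricted (natural) truncated-power basis: K knots give
  K − 1 columns, the first being the identity. Nonlinear columns are divided
  by the squared boundary span for conditioning; any affinely equivalent
  basis gives identical fits. Covariate knots sit at Harrell's default
  percentiles (df 2 → 10/50/90; df 3 → 5/35/65/95; df 4 →
  5/27.5/50/72.5/95), computed with linearly interpolated quantiles on the
  analysis sample *after* complete-case exclusion. Baseline knots use
  uncensored log event times: boundary at min/max, internal at event-time
  quantiles; time-dependent sub-bases use their own 2-df knots at the
  10/50/90 percentiles of log event times.
- **Baseline df.** Not dictated by the analysis being reproduced; default 3
  (4 knots), configurable. A 1-df baseline reproduces the Weibull model
  exactly and is cross-checked against an independent Weibull MLE in the
  tests.
- **Interactions.** An interaction multiplies the partner columns (male
  dummy; (age − 60)/10; smoking dummies) with the *primary* transformed
  covariate column, offset by a fixed per-term centering constant (the log
  of the variable's published median). Centering is a pure
  reparameterisation — the fit, the interaction coefficients and all
  predictions are unchanged — but it removes the near-collinearity between,
  say, a smoking dummy and smoking × ln(urate), keeping the information
  matrix well conditioned. Time-dependent blocks are centered the same way.
- **Fitting.** Full Newton iteration with analytic gradient and Hessian,
  ridge fallback for non-ascent directions and backtracking that keeps the
  hazard positive. Initialisation is deterministic: γ from least squares of
  log(−log Kaplan–Meier survival) on the time basis at event times, all
  other coefficients 0; refits are bit-stable. Convergence requires relative
  log-likelihood change < 1e-9 and max |gradient| < 1e-6 within 200
  iterations. Monotonicity of η in log time is checked at event times after
  fitting, not constrained during it. A singular information matrix
  (separation) is flagged with a warning, coefficients still reported.
- **df convention.** The model df counts every estimated coefficient except
  the baseline intercept; LR χ² statistics and the shrinkage factor use this
  count.

## Model selection

The selection criteria are prescribed (AIC primarily; BIC and a split-sample
variant as sensitivity analyses) but the search itself was an open design
choice. The implementation fixes a deterministic order: transforms first
(linear, log, rcs 2 df, rcs 3 df), one variable at a time with every other
continuous expansion variable held at log; then forward-stepwise
interactions per variable over sex, age, smoking status, timescale, in that
fixed order, keeping a partner iff it lowers the criterion. In BIC, n
defaults to the number of events (configurable to rows). The split-sample
mode selects on a seeded random half and fits on the other half; no row
appears in both. A "published" preset encodes the published selected
specification so downstream stages can bypass the search. Where the
published table's interaction columns were typographically ambiguous (ALP,
ALT), the preset records one documented reading; bilirubin, AST, GGT,
urate, FEV₁ and waist follow the table directly.

## Performance metrics

Harrell's c counts pairs where the earlier time is an event; same-time
event/censored pairs are comparable (the event member should score higher);
same-time event/event pairs earn half credit, as do score ties. The default
CI uses the infinitesimal-jackknife variance of the pairwise U-statistic; a
seeded bootstrap is available. The published analysis did not state its CI
method, so CI widths are not treated as reproducible. FNI and shrinkage are
the printed formulas, 1 − χ²_ref/χ²_alt and (χ² − df)/χ².

## Screening economics

Costs are 2022 GBP unit costs consumed as printed; no inflation machinery.
Telephone contact is costed for every eligible participant in all
scenarios; follow-up tests for those above threshold under the conventional
model; LDCT for those above threshold under both the conventional and the
scenario model. The cost-per-case denominator is the *unrounded* expected
detections (0.20 × cases among referred) — this is what reproduces the
published £26,944 (= 4,079,330 / 151.4) rather than £27,015 (÷ 151); the
rounded count is reported separately. Intermediate totals are kept at full
precision; only final figures are rounded (£ to the nearest unit,
percentages to 1–2 dp). Eligibility is inclusive ages [55, 74] in whole
years with ever-smoking status; "cases" are referred participants with an
event within the 6-year horizon. Zero detectable cases yields a structured
error, never an infinite cost.

## The synthetic cohort

The generator defines the study conditions; it is not tuned per run.

- **Marginals** follow the published baseline table: category frequencies
  for sex/ethnicity/smoking/alcohol/histories; piecewise-linear quantile
  curves for age and Townsend score (matching the published median and IQR,
  with plausible end-points); normals for waist and FEV₁; log-normals for
  pack-years (smokers only) and all blood measurements, with log-scale
  location/spread solved from the published median and IQR. Asbestos
  exposure prevalence is unpublished; the config default is 5 %.
- **Dependencies** are a deliberately small explicit set: pack-years only
  for ever-smokers; FEV₁ declining in age and pack-years with a sex-specific
  level; FEV₁/FVC ratio centred near 0.75 and declining with age and
  pack-years (so airway obstruction concentrates in the screening-eligible
  group, reproducing the ~35 % obstruction / ~4.5 % AST:ALT > 2 incidental
  rates); ALT and AST share a latent log-scale factor (ρ = 0.75). No full
  copula: unpublished joint structure is deliberately not invented.
- **Events** come from a user-specified generating hazard (default: Weibull
  baseline with log time slope 1.1, plus log, interaction and
  time-dependent covariate effects) by inverse-transform sampling — closed
  form in the Weibull case, vectorised bisection otherwise, with an upfront
  check that the cumulative hazard is invertible for every subject
  (non-monotone configurations are rejected with a diagnostic). The
  intercept −13.55 was calibrated once so the default cohort shows a ~0.5 %
  event fraction; the recovery-study variant targets ~5 % (~1,000 events at
  n = 20,000) so coefficient recovery is informative.
- **Censoring**: entry uniform over a 4-year recruitment window with one
  administrative end date (potential follow-up uniform on [5.1, 9.1] years)
  plus independent exponential death censoring at 0.007/year, giving the
  ~7-year median follow-up with IQR close to the published 6.4–7.7.
- **Missingness** is injected MCAR per variable at the published rates
  (complete-case analysis is the target, so MAR machinery is unnecessary).
  Because per-variable missingness is independent, the complete-case
  fraction (~50 %) is lower than in the real cohort, where missingness
  clusters by assay visit; this affects only the effective analysis sample
  size, not the validity of complete-case comparisons.

What passing tests on this cohort do **not** show: that the real cohort's
joint covariate distribution, discrimination level (the synthetic c-index
runs slightly higher than the published ~0.805–0.819 band) or absolute
referral counts are reproduced. They do show that the estimation machinery
is correct (closed-form, oracle and recovery checks), that richer nested
scenarios add prognostic information, and that the economics arithmetic
reproduces the published table exactly from printed inputs.

## Problem sizes

The default analysis cohort is 50,000 participants (the published cohort is
roughly ten times larger); the test suite uses 20,000–30,000 where fits are
involved and 50 seeds × 20,000 for the recovery study. These sizes keep the
whole pipeline interactive while leaving hundreds of events per fit.

## Known limitations

No delayed entry, frailty, cure fractions or penalised estimation; no
multiple imputation (complete-case only, by design); QALY-level
cost-utility modelling, repeat screening rounds and overdiagnosis are out
of scope. The split-sample and BIC selection modes are implemented and
tested but the shipped analysis scripts default to AIC on the full sample.
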