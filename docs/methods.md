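# Methods

`centrevar` implements a provider-profiling analysis for multicentre
in-hospital cardiac arrest (IHCA) cohorts: how much do hospitals differ
in their outcome and process-of-care indicators once chance and case-mix
are accounted for, and is it meaningful to rank them?

## Statistical model

For patient *i* in centre *j*, outcomes are modelled with centre random
intercepts on the logit scale:

* **In-hospital mortality** (binary):
  `logit P(death_ij) = x_ij' beta + u_j`, `u_j ~ N(0, tau^2)`.
* **Cerebral Performance Category at discharge** (CPC, ordinal 0
  asymptomatic … 5 dead), proportional odds:
  `logit P(Y_ij <= k) = theta_k - (x_ij' beta + u_j)`, so a positive
  coefficient means higher odds of a *worse* category. Death is the top
  category, which ties the two outcomes together (see the generator).
* **Time to advanced life support** (minutes): linear mixed model.
* **RRS reporting** (was any ward early-warning score charted in the
  24 h before arrest): mixed logistic.

The case-mix adjustment set is age, Charlson comorbidity index,
pre-arrest modified Rankin scale and pre-arrest CPC. Comparing the
unadjusted with the adjusted random-intercept distribution separates
case-mix-driven from residual between-centre variation.

Heterogeneity metrics:

* **Median odds ratio** `MOR = exp(sqrt(2) * tau * Phi^-1(0.75))`
  — the median odds ratio between two randomly drawn centres (higher
  over lower); 1 means no between-centre variation. The percent decrease
  on adjustment is computed on the MOR scale and reported to the nearest
  integer percent.
* **Rankability** `rho = tau^2 / (tau^2 + median_j(s_j^2))` — the share
  of between-centre variation not attributable to chance. `s_j` is the
  *sampling* standard error of centre *j*'s unshrunken intercept
  deviation (inverse Fisher information given the fixed effects), not
  the empirical-Bayes posterior SD: the posterior SD tends to `tau`
  itself as `tau -> 0`, which would floor rankability at 0.5 under pure
  noise instead of driving it to 0. The aggregation over centres is the
  median by default (mean available via configuration).
* **Nagelkerke R^2** for the fixed-effects case-mix models: Cox–Snell
  `1 - exp(2(l0 - l1)/n)` rescaled by its maximum `1 - exp(2 l0 / n)`.
* **Caterpillar data**: empirical-Bayes posterior means with
  `u ± 1.96 * posterior SD` intervals, ordered by the unadjusted
  estimate, centres anonymised with stable hashed labels.

## Estimation

All fits are implemented in the package. Fixed effects: IRLS (binary),
BFGS with an analytic gradient on a log-difference threshold
parameterisation that keeps `theta` strictly increasing (proportional
odds), OLS (gaussian). Random-intercept models maximise the marginal
likelihood with the centre effect integrated out by *adaptive*
Gauss–Hermite quadrature: per-centre posterior modes are found by a
vectorised damped Newton ascent, the quadrature grid is centred and
scaled at the mode, and the default is 15 nodes for binary outcomes and
the Laplace approximation (one node) for ordinal outcomes, both
configurable. The gaussian mixed model uses the closed-form marginal
likelihood with fixed effects profiled out by GLS and is estimated by
maximum likelihood (not REML) so that log-likelihoods are comparable
across nested models; it reproduces `statsmodels` `MixedLM(reml=False)`
exactly on test data, and the binary AGQ fit reproduces `lme4::glmer`
(nAGQ = 15) to all printed digits on a shared fixture.

`tau` is optimised as `log tau` with a boundary check: fits driving
`tau` below 1e-3 are reported as `tau = 0` (a legitimate boundary
solution, not an error). Convergence uses relative likelihood change
below 1e-11 / gradient norm below 1e-7 with a 300-iteration cap; Wald
standard errors come from the finite-difference observed information of
the marginal likelihood. Complete separation is flagged as
non-convergence with a diagnostic message rather than an exception.
Complete-case rows are used inside each fit; missing data are handled
upstream by multiple imputation.

## Missing data

Chained-equations multiple imputation (default m = 5, 10 cycles): each
incomplete field is regressed on all other fields — outcomes included —
with predictive-mean matching (k = 5 donors, type-1 matching) for
continuous fields, logistic draws for binary fields and
proportional-odds draws for ordinal fields (the day/evening/night shift
is treated as ordered). Parameter uncertainty is propagated by refitting
each imputation model on a bootstrap resample of the observed rows, an
approximate-Bayesian variant of the usual posterior draw. The discharge
CPC is imputed conditionally on observed mortality so the death/CPC-5
equivalence survives imputation. Coefficients are pooled by Rubin's
rules (within-variance W, between-variance B, total `W + (1+1/m)B`,
small-sample degrees of freedom). The random-intercept SD has no
per-imputation SE attached, so `tau` is pooled as a geometric mean
(log scale) by default; an arithmetic mean on the SD scale is available
via `pool_tau_scale="sd"` — the pooling scale for variance components is
a genuinely open choice and is therefore surfaced in configuration.
A complete-case sensitivity analysis replaces imputation when
`complete_case=True`.

## Synthetic cohorts

The generator emulates the statistical structure of a ~700-patient,
12-centre Dutch IHCA cohort; it makes no attempt to model resuscitation
physiology. One latent proportional-odds process generates discharge
CPC; mortality is its top category, so `mortality = 1  <=>  CPC = 5` by
construction, and the induced mortality model is exactly logistic with
the same linear predictor. Defaults (all overridable):

* 12 centres with sizes {15, …, 140} summing to 701, median 49 — the
  skewed participation typical of voluntary registries.
* `tau_outcome = 0.19` (true MOR ≈ 1.20), `tau_process = 1.1` for RRS
  reporting (MOR ≈ 2.9), `sigma_als_centre = 0.8` min for centre shifts
  in time to ALS — magnitudes chosen to be realistic for outcome vs
  process indicators in hospital-comparison studies, where process
  indicators vary far more between hospitals than casemix-adjusted
  outcomes.
* Case-mix log-odds: Charlson 0.157, pre-arrest MRS 0.095, pre-arrest
  CPC 0.358, age 0.0223 per year — odds ratios of 1.17, 1.10, 1.43 and
  1.25 per decade, typical effect sizes for pre-arrest frailty markers.
* Thresholds `theta` calibrated so the marginal discharge distribution
  has ~67% deaths and ~18% full recovery at the default case-mix mix
  (median age 69, median Charlson ~2, ~78% pre-arrest CPC 0).
* Context marginals: ~79% witnessed, ~26% shockable rhythm, location
  mostly ward/ICU/CCU, day/evening/night ≈ 35/49/16%.
* MAR missingness: logistic in one observed driver (age by default)
  with the intercept calibrated to the target rate; defaults put 1.7%
  on discharge CPC and 3–4% on pre-arrest scales.

One master seed feeds named substreams (centre-level draws,
patient-level draws, missingness) so adding a downstream stage never
perturbs earlier draws; generation is bit-for-bit reproducible.

What the generator deliberately omits — and hence what passing tests do
*not* demonstrate about real data: centre-correlated case-mix (real
referral patterns cluster frail patients in particular hospitals, which
is exactly what makes adjustment consequential; here the decrease of the
MOR on adjustment fluctuates around zero), non-proportional odds,
informative (MNAR) missingness, within-centre temporal drift, and any
causal pathway from process indicators to outcomes.

## Pipeline

`run_profile` chains: simulate (or load CSVs) → exclude centres
contributing ≤ 10 patients (the default threshold is exclusive, so a
centre with exactly 10 patients is dropped) → impute → fit all models on
each completed dataset → pool → metrics → structure-of-care Fisher
tests → descriptives → validated JSON report (schema ships with the
package), with optional SVG caterpillar and stacked-bar figures. The
report is byte-identical under a fixed seed. Structure-of-care
indicators (CPR training at least twice yearly, 24/7 intensivist, 24/7
ALS-certified physician) are tested on observed CPC scores only, with
categories 4 and 5 collapsed, using a fixed-margin Monte-Carlo Fisher
exact test (default 1e5 tables); a post-hoc proportional-odds model
re-examines the training effect with case-mix adjustment. The effect of
time to ALS on CPC is adjusted for the back-door set {weekend, shift,
witnessed, RRS reported}. The effect of RRS reporting *on outcome* is
refused by design: an arrest-only cohort has no non-arrest control
group, so that effect is not identifiable.

Two published summary figures are mutually inconsistent in the source
literature this design follows (an abstract reporting 218/32% survivors
versus a results section reporting 230/33%); the pipeline treats the
results-section figure as canonical wherever such numbers are used as
inputs, and this note records the discrepancy rather than resolving it
silently.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make Monte-Carlo error
negligible relative to each tolerance while staying desk-scale: 4e7
pairs for the MOR sampling oracle; 50 centres × 200 patients × 20 seeds
for MOR recovery; 200 replicates for Rubin-CI coverage; 500 draws for
the Fisher null calibration; 400 centres × 120 patients for `tau`
recovery. The full pipeline at study scale (701 patients, m = 5) runs
in well under a minute.

## Known limitations

* The ordinal mixed model defaults to Laplace; with very small centres
  and strong heterogeneity, `tau` can be slightly biased downwards
  (raise `quadrature_nodes`).
* Rankability depends on the SE aggregation choice (median vs mean)
  when centre sizes are very unbalanced.
* With only ~12 centres, `tau` — and hence MOR and rankability — is
  estimated with substantial sampling error; single-cohort rankability
  near 0.5 is compatible with no true outcome heterogeneity.
* PMM requires a few dozen observed donors to behave; fields that are
  almost entirely missing are rejected rather than imputed.
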