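# Methods

## Scope and model family

`phenolmm` implements a digital-phenotyping analysis for psychotic-disorder
outpatients monitored continuously by a wrist-worn device and rated monthly
on the five PANSS symptom dimensions (positive, negative,
cognitive/disorganization, depression/anxiety, excitement/hostility).  The
pipeline has four stages:

1. **Window features.**  From each 5-minute sensor window: the short-time
   energy (STE) of the Euclidean norm of the 3-axis accelerometer and
   gyroscope signals, `STE = Σ_j x_j²`; the normal-to-normal (NN) interval
   count and the RMSSD of successive differences from artifact-cleaned
   interpulse intervals.  Per day: the sleep:wake hour ratio and steps per
   minute, on days with ≥ 18 h of recording.
2. **Monthly aggregation.**  Follow-up months are 30-day blocks from
   enrollment.  Months with < 720 wake or < 480 sleep windows are excluded.
   Twenty monthly phenotypes: mean and SD of the four window features,
   separately in wake and sleep (16), plus mean and SD of the sleep:wake
   ratio and of steps/minute (4).
3. **Mixed-model selection.**  Per (phenotype, dimension) pair, a 3-step
   maximum-likelihood LMM chain: (i) random patient intercept; (ii) + AR(1)
   residual correlation, tested by a χ²₁ likelihood ratio; (iii) + random
   slope on the phenotype with unstructured 2×2 random-effect covariance,
   tested against the current best model by the equal-weight ½χ²₁ + ½χ²₂
   mixture (a variance parameter on its boundary plus a covariance).
   Step 1 screens all 100 pairs at p < .05 AND Cohen f² = Rm/(1−Rm) ≥ 0.01,
   uncorrected by design.
4. **Confounder protocol.**  Random-intercept screens of covariates
   (gender, diagnosis group, chlorpromazine and fluoxetine equivalents,
   follow-up time) against all 20 phenotypes and 5 dimensions with the same
   double gate; covariates significant for *both* members of a retained
   pair enter an interaction model (phenotype + covariate +
   phenotype×covariate) on the pair's best random structure.

## Estimation

All models are fitted by marginal Gaussian **maximum likelihood** (never
REML), so −2LL differences are valid for both fixed- and random-part
comparisons.  For patient *i* with design `X_i`, random-effect design
`Z_i` (a ones column, plus the phenotype column when a random slope is
present):

    V_i = Z_i G Z_iᵀ + σ² R_i(ρ),   R_i[j,k] = ρ^{|j−k|}

with `R_i` the identity without AR(1).  The AR(1) index is the
within-patient visit order; months missing from the table count as unit
steps (a documented simplification — calendar-gap indexing is a sensitivity
switch candidate, not implemented).

Fixed effects are profiled out by GLS and the residual variance in closed
form, leaving 1–4 free parameters: log variance ratios and Fisher-z
correlations, optimized by L-BFGS-B from ≥ 3 dispersed deterministic starts
(plus warm starts mapping a nested fit to the larger model's boundary, which
guarantees nonnegative LR statistics up to line-search noise).  Outcome and
predictors are standardized internally and estimates mapped back, so
optimization is scale-free across phenotypes whose units span seven orders
of magnitude.  Likelihood evaluation is factorized per patient and batched
over equal group sizes; no dense all-observations covariance is ever formed.
Convergence failure is recorded on the fit (`converged=False`), not raised;
the selection driver reacts per its fallback rule (random-slope fit retried
with AR(1); both failing, the pair keeps its step-1/2 winner, flagged).

**Inference.**  Wald t-tests are two-tailed with Satterthwaite-type df:
`df = 2·Var̂(cᵀβ̂)² / Var[Var̂(cᵀβ̂)]`, the denominator by the delta method
over the variance parameters using the observed information (numerical
Hessian of the β-profiled negative log-likelihood), clamped to
[1, n−p] with a fallback to n−p when the information is singular (e.g.
variance ratios at the boundary).  Because the information is ML-based, the
balanced-design intercept df comes out near G rather than the classical
G−1; at cohort sizes the difference is < 3%.

**Effect size.**  The marginal pseudo-R² is the Nakagawa-style proportion
`Rm = var(Xβ̂) / (var(Xβ̂) + σ²_intercept + σ²_resid)` and f² = Rm/(1−Rm).
It is defined only for the random-intercept structure, where the residual
variance is a scalar; requests on AR(1)/random-slope fits raise.  (The
source analysis reported only the software's "coefficients of
determination" output without a formula; the Nakagawa form is this
package's documented choice.)

**Model-selection chain.**  When step 2 (AR(1)) wins, step 3 adds the
random slope *on top of* the AR(1) structure and the mixture null is
retained although two-plus parameters move — documented as an
approximation.  Whether the original analysis kept AR(1) under the
random-slope model is ambiguous; the nested chain here is a design choice.

## Synthetic cohort

No patient data are deposited, so a seeded generator supplies every input.
Its defaults are the stated world of the cohort the analysis targets:

| parameter | default | rationale |
|---|---|---|
| patients | 38 | cohort size |
| follow-up | rounded truncated normal on [1, 26], SD 7.2, parent mean solved so the truncated mean is 11.8 | published follow-up distribution |
| wake / sleep | 16 h / 8 h per day, one consolidated sleep block near 23:00 (jittered onset/duration) | typical actigraphy |
| window grid | half-open 5-minute bins aligned to midnight, 30-day months | unambiguous binning; uniform thresholds |
| window features | state-dependent Gaussian targets (e.g. NN ≈ 360 wake / 300 sleep per 5 min; RMSSD ≈ 30/45 ms; wake motility ≫ sleep) with patient-level, month-level and window-level variance components | wrist-PPG/actigraphy scale; sleep shows lower motility and heart rate, higher vagal tone |
| month-level deviations | half shared latent factor, half feature-specific | phenotypes co-vary month to month |
| missingness | 5% window drop, 5% non-wear days, 5% missed visits | light, realistic non-wear |
| PANSS | β₀ per dimension ≈ 7–12, random intercept SD 2, residual SD 1.5, AR(1) ρ = 0.3, no planted slopes | mildly symptomatic, stable outpatients; a *null* world by default |

PANSS scores are the analysis's own largest model run forward:
`score_it = β₀ + b₀ᵢ + (β₁ + b₁ᵢ)·x_it + ε_it`, with the 2×2
intercept–slope covariance implied by the SDs and correlation (multiple
slope phenotypes share the intercept correlation through a one-factor
construction, guaranteeing positive semidefiniteness) and stationary AR(1)
errors at marginal SD `residual_sd`.  The phenotype `x` entering the model
is the *aggregate of the generated windows*, so the downstream analysis
table recovers exactly the x that generated y.  Scores are clipped at each
dimension's floor (the item count of the standard five-factor PANSS model:
3/6/3/3/4); integer rounding is off by default — the conditional
distribution of PANSS given phenotypes is not specified anywhere, so both
behaviors are configuration, not assertion.

Randomness is partitioned per patient with `numpy` seed sequences keyed by
(seed, stream, patient index): adding patient 39 never perturbs patients
1–38.  Scores are generated at dimension level; item-level generation and
an item→factor mapping are out of scope, as the analysis consumes only
dimension scores.

**Raw-stream mode** re-expresses each window's targets as payloads: 3-axis
sample blocks rescaled so the extracted STE reproduces the target exactly,
and a jittered renewal process of interpulse intervals whose count and
successive-difference SD hit the NN/RMSSD targets, plus occasional
out-of-band artifact intervals (150/5000 ms) for the cleaning rule to
remove.  It exists to exercise the feature path end-to-end and is intended
for small cohorts.

**Monthly-panel fast path.**  `generate_monthly_panel` emits the modelling
table directly from the same generative law (monthly means from patient +
month components plus an aggregation-noise term sized to the window counts
a full month would average over), sharing the PANSS code with the full
path.  Monte-Carlo suites needing hundreds of cohorts use it; the full
window path and the panel agree in their first two moments by construction
but the panel does not reproduce window-level artifacts (missingness
inside a month, integer NN counts).  A green Monte-Carlo test therefore
establishes calibration of the *statistical* machinery, not of the raw
feature extraction — which has its own exact tests.

## What the generator does not emulate

Real PPG waveforms and firmware formats; a sleep/wake classifier (labels
are generated, and in real-data mode ingested — the classifier of the
source device is proprietary and undescribed); GPS phenotypes; item-level
PANSS; medication-equivalent conversion tables (equivalents are emitted
directly); informative (symptom-linked) missingness — dropout here is
completely at random, so the pipeline's excluded-month behavior under
missing-not-at-random data is untested, mirroring the source analysis's own
limitation.

## Numerical choices and degenerate inputs

* Artifact cleaning retains intervals in [300, 2000] ms and within ±20% of
  the running median of the previous 10 retained intervals (the original
  preprocessing is described only by citation; these defaults are exposed
  in configuration).  The rule is idempotent and order-preserving; an
  interval is assigned to the window containing its end time.
* Empty 5-minute windows yield a missing STE (dropped), never zero; RMSSD
  is missing below 2 NN intervals and such windows leave the RMSSD
  aggregate only.
* A window's state is the majority label of its samples, ties → wake.
* Monthly SDs are across 5-minute windows by default; across daily means is
  a config switch (`sd_scope`), since the original's choice is unstated.
* Ratings are aligned to the 30-day block that *ends* at the visit
  (`alignment: preceding`, default); `same` shifts by one block.
* Variance ratios are bounded in log space at ±16, correlations at
  |z| ≤ 6; σ̂² is floored at 1e−300 to survive exact-interpolation inputs.
* LRT statistics are clamped at 0; a pre-clamp deficit beyond 1e−6 raises a
  diagnostic error suggesting optimizer restarts (warm-started chains make
  this unreachable in the drivers).
* Multi-level-factor screens use a joint Wald F with denominator df = n−p;
  the Satterthwaite scheme is defined per 1-df contrast and no multi-df
  extension is prescribed anywhere.
* p-values are carried at full precision; the report layer prints 2–3
  decimals with `<.001` below 0.001.

## Known limitations

* Satterthwaite df from ML information runs slightly large in small
  samples (G vs G−1); exact df agreement with the original analysis's
  proprietary software output is unknowable and not claimed.
* The AR(1) clock ignores calendar gaps from excluded months.
* The mixture null under an AR(1)-retained step 3 is an approximation.
* The generator's clipping at dimension floors mildly truncates the
  Gaussian model it otherwise follows; recovery/calibration suites use
  truths whose intercepts sit far from the floors or disable clipping, and
  say so.
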