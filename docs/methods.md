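# Methods

This note documents the statistical model behind `dietbrain`, the
parameters that matter, and the design choices made where more than one
defensible option existed. It describes what the code computes; every
empirical number quoted is one the test suite or `scripts/acceptance.py`
recomputes.

## 1. The diet-quality score

The exposure is a predefined 0–15 index of adherence to Dutch dietary
guidelines for pregnant individuals. Each of 15 food components
contributes a score in [0, 1]:

| kind | components | rule |
|---|---|---|
| adequacy | vegetables (≥200 g/d), fruit (≥200 g/d), whole grains (≥90 g/d), legumes (≥135 g/wk), nuts (≥15 g/d), dairy (≥300 g/d), fish (≥100 g/wk), tea (≥450 g/d) | `min(intake / cutoff, 1)` |
| ratio | whole grains / total grains; soft fats and oils / total fat | the fraction itself |
| moderation | red meat (≤375 g/wk), sugar-containing beverages (≤150 g/d), salt (≤6 g/d) | `clamp(2 − intake/cutoff, 0, 1)` |
| binary | alcohol | none = 1, any = 0 |
| categorical | folic-acid supplementation | periconceptional = 1, started in first 10 gestational weeks = 0.5, none = 0 |

**Reverse coding.** Guideline-based indices state that moderation
components are reverse-coded without fixing a functional form. We use
`clamp(2 − intake/cutoff, 0, 1)`: full credit at or below the
recommended maximum, declining linearly to zero at twice the maximum.
This keeps the ratio-based construction of the adequacy components, is
continuous, and awards exactly 1 when the guideline is met. A
consequence worth noting: zero intake of a moderation food scores 1, so
the all-zero intake record does *not* score 0 overall.

**Undefined ratios.** A ratio with a zero denominator (no grains, no
fats consumed) is scored 0 with a warning — unobserved quality earns no
credit.

**Units.** Weekly components (legumes, fish, red meat) are scored in
g/week without conversion; the registry (`registry.json`) records the
unit of every component and is the single source of cut-offs.

Scores are never rounded internally; additivity (total = Σ components,
leave-one-out identity) holds to 1e-9 and is property-tested over
arbitrary non-negative records.

## 2. The synthetic cohort

The generator emulates the statistical structure a pregnancy-nutrition
neuroimaging cohort presents to the analysis, so that every pipeline
stage has a ground truth to be checked against.

### Structural model

For each dyad, with independent standard-normal innovations throughout:

1. **Latent socioeconomic factor** `U ~ N(0,1)`.
2. **Healthy-diet factor** `F = λU + √(1−λ²) ε`, where
   `λ = confounding_strength` (default 0.3).
3. **Component intakes**: each continuous component is log-normal,
   `intake_i = cutoff_i · exp(μ_i ± σ_i x_i)` with
   `x_i = τF + √(1−τ²) e_i` (sign flipped for moderation components so a
   healthy population eats less of them); alcohol and folic-acid are
   thresholded on the same kind of latent, with fixed marginals (50% no
   alcohol; 45 / 30 / 25% periconceptional / first-10-weeks / none).
4. **Covariates**: income (12 / 22 / 66%), education (65.6% high),
   national origin (63.9% Dutch), smoking (78.5 / 9.2 / 12.3%),
   breastfeeding, maternal age (31.2 ± 4.6 y) and the psychopathology
   GSI are generated from `U` via loaded continuous scores, categorical
   ones by thresholding at the target frequencies. Energy intake is a
   linear function of the generated food masses plus noise.
5. **Outcome-side confounding** enters as a standardized linear index
   `W` of the *observed* covariates (income, education, origin, smoking,
   GSI, maternal age). Socioeconomic position therefore affects brain
   and IQ through its measurable expressions: the model-1 covariate set
   removes the confounding exactly, while the crude (unadjusted)
   diet→outcome slope remains inflated — both directions are tested.
   Routing the outcome effect through the latent `U` itself was
   rejected: covariates that only proxy a latent confounder leave an
   irreducible bias in the adjusted slope, which would contradict the
   generator's defining requirement that configured effects be
   recoverable by covariate adjustment.
6. **Child diet score** (0–10 scale, 4.5 ± 1.2): correlated with the
   standardized maternal score at `r = 0.29` and carrying a direct
   effect into volumes and IQ. The direct effect is sized from the gap
   between the configured model-1 and model-2 targets
   (`d = (B₁ − B₂)·score_sd/r`), which makes the model-2 attenuation a
   real feature of the data-generating process; structural direct
   effects then equal the model-2 coefficients.
7. **Brain volumes at 10 y**: cerebral white (440 cm³), gray (600 cm³),
   subcortical (61 cm³) and a remainder compartment (brainstem,
   cerebellum, ventricles; 130 cm³) are generated separately, each
   `α + B·(score − 7.8) + d·child + γ·W + noise`, and summed to the
   total brain volume — so the total-brain coefficient is the sum of
   its parts by construction. Intracranial volume adds a strictly
   positive log-normal margin, guaranteeing
   white + gray + subcortical ≤ total ≤ intracranial row by row.
   Age-14 volumes add a growth increment with its own noise and slope
   deltas, reproducing slightly attenuated age-14 coefficients.
   Intercepts and noise SDs (45/55/8/20 cm³) are free defaults; the
   coefficient-recovery properties do not depend on them.
8. **IQ at 14 y** depends structurally on total brain volume at 10 y —
   the single generative mediator:
   `IQ = 103.7 + c′·(score − 7.8) + b·(TBV₁₀ − 1231) + d·child + γ·W + noise`,
   with `b` solved from the configured total effect (0.65) and
   proportion mediated (0.077): `ACME = 4.54·b = 0.077·0.65`, and `c′`
   chosen so the model-1 total effect equals 0.65. White, gray and
   subcortical volumes mediate through their correlation with the total
   (a common-cause structure), avoiding four free mediator slopes.
   Subtest t-scores (1–19, clipped) carry the diet signal through
   vocabulary and matrix reasoning only; digit span and coding get none.
9. **Nutrient proxies** (dietary fiber, saturated fat) are linear in the
   adequacy/moderation intakes plus noise, supporting the sign-only
   internal-validity check of the score (positive with fiber, negative
   with saturated fat).

### Intake calibration

`calibrate_intakes(mean, sd)` searches two scalars — a global healthy
shift δ applied to every log-median (subtracted for moderation
components) and the common-factor loading τ — by alternated Brent root
finding on seeded Monte Carlo moments (60,000 simulated mothers, common
random numbers, fixed internal seed). Convergence tolerance is 0.01 on
the mean and 0.02 on the SD; results are cached per target. Because the
alcohol and folic-acid marginals are fixed, achievable means span
roughly [1.2, 14.1]; the exact boundary targets (15, 0) and (0, 0) are
returned as degenerate configurations (at-cutoff intakes, or zero
adequacy intakes with moderation intakes at twice the cut-off), and
unreachable targets raise with diagnostics.

### Missingness

`inject_missingness` blanks covariate cells only (GSI 10%, smoking 7%,
breastfeeding 15%, gestational folate concentration 20%, maternal age 3%
by default) with probability proportional to
`exp(0.8·[income<1200€] + 0.4·[income 1200–2200€] + 0.5·[low education])`,
normalised to the configured marginal rate — missing at random given the
always-observed income and education. Exposure intakes, mediators and
outcomes are never blanked, matching the scope of the imputation in the
analysis the pipeline mirrors.

## 3. Multiple imputation and pooling

Chained equations (m = 10 chains, 50 sweeps by default; both
configurable): per sweep each incomplete column is regressed on all
other variables using the rows where it is observed. Continuous columns
use a Bayesian linear draw — σ² from the scaled inverse-χ², β from
N(β̂, σ²(XᵀX)⁻¹), plus residual noise; categorical columns use a
multinomial-logistic model fit on a bootstrap resample (parameter
uncertainty) with categories drawn from the predicted probabilities, and
a logged frequency-draw fallback on non-convergence. Predictive-mean
matching is deliberately not implemented: regression draws are simpler,
directly testable, and adequate for MAR covariates. The imputation model
is congenial — exposure, mediators and outcomes all enter as predictors.

Rubin pooling: point = mean of per-imputation estimates, total variance
`T = W + (1 + 1/m)B`, intervals from a t reference with Barnard–Rubin
degrees of freedom when a complete-data df is available. When all
per-imputation estimates coincide (B = 0), the reference collapses to
the complete-data one, so imputing a complete table reproduces the
complete-data analysis exactly.

## 4. Association models

Ordinary least squares via statsmodels on an explicitly constructed
design matrix. Categorical covariates enter as indicator contrasts with
reference levels chosen as the majority categories (income >2200€,
never-smoked, Dutch origin, high education, boys, no/short
breastfeeding); this affects only covariate coefficients, never the
exposure slope. The child-age covariate follows the outcome's assessment
wave. Energy is adjusted as an ordinary covariate (not by the residual
method). p-values use the t distribution with residual df. Missing cells
raise rather than being silently dropped; rank-deficient designs raise
naming the collinear columns.

Benjamini–Hochberg: `q_(i) = min_{j≥i} m·p_(j)/j` capped at 1, flags at
q ≤ 0.05, applied within the 8-test volume family and the 5-test IQ
family (to pooled p-values when imputation is active). The
implementation is cross-checked in tests against both a brute-force
step-up oracle and statsmodels' `multipletests`.

Sensitivity analyses: stratification by national origin (stratifier
dropped from the design), optional extra covariates (breastfeeding,
intracranial volume at the matching age, gestational folate), and the
leave-one-food-component-out analysis, where the exposure becomes the
14-component score and the excluded component's raw intake joins the
covariates (constant intakes are dropped, keeping the design full rank).

## 5. Quasi-Bayesian mediation

Mediator model `M ~ X + C` and outcome model `Y ~ X + M + C` are fit by
OLS; `n_sims` (default 1000, minimum 100) parameter vectors are drawn
from the normal approximation — the two models independently, which is
an approximation since they share data. Per draw, ACME = a·b, ADE = c′,
total = their sum, so ACME + ADE = total holds exactly per draw.
Intervals are 2.5/97.5 percentiles of the draws.

Point estimates: mean of draws for the effects (median available by
option). The proportion mediated ACME/total is summarised by the
**median** of the per-draw ratios: the ratio is heavy-tailed whenever a
total-effect draw crosses zero, making the mean unusable exactly when
uncertainty matters; the median matches common practice in reference
implementations. When the total effect's CI includes zero the result
carries an `unstable_denominator` flag and a warning. Even so, the
replicate-averaged estimated proportion sits slightly above the
generative 7.7% (by roughly half a percentage point at n = 2223) — the
ordinary small-sample bias of a ratio whose denominator is estimated
with SE ≈ 0.22; it shrinks with n and stays well inside the acceptance
band.

Across imputations, the m × n_sims draws are concatenated (a mixture
over completed datasets) before summarising; percentile intervals remain
valid for the mixture, whereas Rubin's rules on ACME would presume
normality the ratio statistics do not have.

## 6. Pipeline and reproducibility

One global seed deterministically derives per-stage seeds (all < 2³¹)
via a seed sequence; every artifact records the configuration hash, and
a MANIFEST marks incomplete runs with the failing stage named. Cohort
description follows the convention mean/SD for roughly symmetric
continuous variables, median/IQR when |sample skewness| > 1 (our
criterion — the convention itself never states one), and percentages for
categorical variables.

## 7. Problem sizes used in tests

Unit tests run on cohorts of 350–20,000 dyads. The recovery checks use
100 replicates of n = 2223 dyads (the cohort size the design emulates)
with 1000 mediation simulations each, a 100,000-dyad cohort for the
calibration targets, and 500 replicates of n = 250 under a global null
for the false-discovery check — sizes at which Monte Carlo error is
comfortably below the tolerances being asserted.

## 8. Known limitations

- The generator emulates moments, effect sizes and missingness
  structure, not real data's measurement error (FFQ under-reporting),
  non-response/selection, genetic confounding, or non-linear
  dose–response; passing recovery tests shows the *pipeline* is correct
  under its assumed model, not that the substantive estimates would be
  unbiased in a real cohort.
- Outcome noise SDs are free defaults: confidence-interval *widths* are
  not calibrated to any real dataset, only coverage of the generative
  truth is.
- Mediator and outcome parameter draws are independent; exposure ×
  mediator interaction and sensitivity analysis for sequential
  ignorability are out of scope.
- The chained-equation imputer implements one method per column type;
  passive imputation, interactions and per-column custom methods are
  out of scope.
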