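# Methods

This note documents the statistical models and procedures implemented in
`volrely`, the numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Data model

All analyses consume one tidy table of volume observations with columns
`subject_id, method, roi, session, time_months, volume`. The key
`(subject_id, method, roi, session)` is unique; volumes are in mm³ (or any
fixed unit — every headline statistic is either scale-invariant or reported
with its unit); time is always months from baseline. Left and right
hemispheres are distinct ROIs (`hippocampus_L`, `hippocampus_R`) and are
analyzed independently throughout. The file reader rejects duplicate keys,
malformed numerics and non-positive volumes with row-numbered messages;
missing sessions are rejected rather than imputed, so every analysis runs
on complete pairs only.

## Accuracy metrics

The volume percentage error of a prediction against manual ground truth is
`VPE = 100·(v_pred − v_gt)/v_gt`, signed (underestimation negative) and
invariant to common rescaling. Per method × ROI the pipeline reports the
median, mean, 25th/75th percentile and sample SD (n−1 denominator) of the
VPE distribution; percentiles use linear interpolation between order
statistics. Pearson correlations between predicted and manual volumes are
banded very strong (> 0.9), strong (0.7–0.9), moderate (0.4–0.7), weak or
negligible (< 0.4); the cut points are read as strict inequalities, so an
exact boundary value falls into the lower band.

## Test–retest metrics

The volume percentage difference between sessions is
`VPD = 100·2·|v_test − v_retest|/(v_test + v_retest)` — symmetric, zero iff
equal, bounded by 200, scale-invariant. Reliability is the intraclass
correlation for a single rater under the consistency, two-way mixed-effects
model: with between-subject mean square MS_R and residual mean square MS_E
from the two-way ANOVA without interaction,

    ICC = (MS_R − MS_E) / (MS_R + (k − 1)·MS_E).

The consistency form absorbs a constant session offset into the session
effect, so a fixed test–retest bias does not lower the ICC. The 95% CI is
the standard F-based interval: F = MS_R/MS_E on (n−1, (n−1)(k−1)) degrees
of freedom, divided/multiplied by the two-sided critical F and mapped back
through (F′ − 1)/(F′ + k − 1). The CI method is a design choice (a
bootstrap would also be defensible); it is the conventional companion of
this ICC form. Bands: poor below 0.75, good from 0.75 through 0.95,
excellent above 0.95. When MS_E = 0 the estimate and both CI bounds are the
degenerate point 1.

## Hypothesis-testing battery

- **Normality gate**: one-sample Kolmogorov–Smirnov against a normal with
  mean and SD estimated from the sample, at α = 0.05. Estimating the
  parameters makes the naive KS conservative (true rejection rate below
  nominal); this is documented rather than corrected (no Lilliefors
  adjustment) because the battery pins the plain procedure.
- **Location**: the gate runs on each of the two compared samples; if
  neither rejects, a paired t-test, otherwise the Wilcoxon matched-pairs
  signed-rank test. Accuracy comparisons test |VPE| (configurable),
  test–retest comparisons test VPD. Zero differences are dropped (Wilcoxon
  convention); all-zero input returns p = 1. For n ≤ 25 after zero removal
  the Wilcoxon null distribution is computed exactly by counting sign
  assignments over midranks (doubled to integers, so tied ranks stay
  exact); the two-sided p is min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))) and
  coincides bit-for-bit with full 2ⁿ enumeration. Above 25 the normal
  approximation with tie correction and 0.5 continuity correction is used.
- **Precision**: two-sided F-test on the VPE variances, p doubling the
  smaller tail.
- **Correlations**: Fisher's z-test,
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.
  The compared correlations share the manual volumes, so the independence
  assumption is approximate; the test is implemented as named.
- **Interval comparisons** (ICC, BLME quantities): significant iff neither
  point estimate lies inside the other's interval. The rule could be read
  one-directionally; the symmetric, conservative reading is the default and
  the one-directional variant is available behind `symmetric=False`.
- Significance threshold α = 0.01 for the location/variance/correlation
  tests; no multiple-testing correction is applied (by design, matching the
  evaluation protocol this battery implements).

## Bayesian linear mixed-effects model

For volume V_ij of subject i at time t_ij (months since that subject's own
first session; `normalize_time` enforces baseline 0 per subject):

    V_ij ~ N(α_i + β_i·t_ij, σ²)
    α_i ~ N(α₀, τ²),  β_i ~ N(β₀, ρ²)
    α₀, β₀ ~ N(0, prior_loc_sd²),  σ, τ, ρ ~ HalfCauchy(prior_scale)

with defaults prior_loc_sd = 10 and prior_scale = 5. Those second
arguments are read as an SD and a scale; on raw mm³ volumes (≈ 2000–5000)
they would be absurdly informative, so by default volumes are standardized
by the grand mean/SD before fitting — the scale on which the priors are
weakly informative — and all location/scale summaries are reported on both
the sampled and the raw scale (`mean` vs `mean_raw` etc.). The headline
statistic r = τ/σ is invariant to this choice; it is computed per draw and
summarized by its posterior mean and central 95% credible interval (the
posterior of the ratio, not the ratio of posterior means).

### Sampler

The sampler is a collapsed Metropolis-within-Gibbs scheme, chosen so the
repository stays self-contained and every update is testable against closed
forms:

1. **Scales** (σ, τ, ρ): log-scale random-walk Metropolis against the
   likelihood with both subject effects (α_i, β_i) integrated out
   analytically. Per subject the marginal covariance is
   σ²I + τ²𝟙𝟙′ + ρ²tt′, a rank-2 update whose determinant and inverse have
   closed 2×2 forms (matrix determinant lemma / Woodbury), so each target
   evaluation is a handful of O(n_subjects) vector operations. Targets
   include the half-Cauchy prior and the log-scale Jacobian. Five scans of
   the three scales run per iteration (they are cheap and the scales are
   correlated in the marginal); step sizes adapt toward 44% acceptance in
   batches of 50 during warmup only, so the post-warmup kernel is fixed.
2. **Locations** (α₀, β₀): drawn jointly from their exact bivariate
   Gaussian conditional under the same effect-marginalized model.
3. **Subject effects** (α_i, β_i): refreshed jointly per subject from their
   bivariate Gaussian full conditional (closed-form 2×2 Cholesky).

Collapsing the effects eliminates the funnel geometry that makes centered
Gibbs mix slowly when a variance component (typically ρ) is small relative
to its sampling error; the implementation was validated against an
independent ensemble sampler run on the exact `log_posterior` and against a
conjugate closed-form reduction (τ, σ fixed, ρ pinned at 0). Defaults: 4
chains from dispersed data-informed initial values, 1000 warmup + 1000
retained draws each. Convergence is enforced, not advisory: if any
parameter's split-rhat (computed via arviz) exceeds 1.01 the fit raises a
diagnostic error listing the offenders. Identifiability guard: if no
subject has two distinct timepoints, ρ is unidentifiable and the fit is
refused unless ρ is pinned via `fix_rho` (pinning at 0 reduces β to a fixed
effect). `fix_tau`/`fix_sigma` exist for validation and degenerate designs.

### Cross-method comparison

`compare_blme` applies the CI-overlap rule to r, τ and σ. τ and σ are
compared on the raw volume scale — the decision is equivariant under common
rescaling of both datasets, and the raw scale is the meaningful one when
two methods' grand SDs differ — while r is scale-free. Comparing a
standardized fit against a raw fit is refused.

## Synthetic-data generators

The generators produce tables whose population quantities are known in
closed form, so downstream estimates have analytic targets:

- `simulate_longitudinal` draws from exactly the BLME generative law.
  Subject effects are drawn first, ordered by subject index, from a stream
  separate from the observation noise, so extending the timepoint grid
  leaves subject effects unchanged (reproducible factorial experiments).
  No truncation is applied: on mm³ scales negative draws are astronomically
  unlikely, and on standardized scales negativity is meaningful, so the
  Gaussian law is kept exact.
- `simulate_testretest` draws true volumes N(mu, between_sd²) and two
  sessions with independent N(0, within_sd²) noise; its population
  consistency ICC is between_sd²/(between_sd² + within_sd²). Negative draws
  are rejected and redrawn (count logged and attached to the table) to
  honor the positivity contract; a warning fires if the parameters imply
  more than 1% rejection, since heavy rejection distorts the nominal law.
- `simulate_accuracy` draws truncated-positive ground truths and predicts
  v_gt·(1 + (bias_pct + η)/100) with η ~ N(0, noise_pct²), making the VPE
  of each pair exactly bias_pct + η: VPE mean and SD equal the bias and
  noise parameters by construction. The multiplicative bias-plus-noise form
  is an artifact choice — no generative model for VPE dispersion is implied
  by the evaluation protocol itself — chosen as the simplest law with
  independently controllable bias and precision.

Default study sizes mirror the study designs the pipeline emulates: 45
subjects for test–retest (a submillimeter 3T test–retest cohort size), 40
subjects × 5 visits over 12 months for the longitudinal design, 500
subjects for the accuracy study (same order as a multi-site manual-tracing
dataset). What the generators do **not** emulate: scanner/field-strength
effects beyond variance components, segmentation failures and outliers,
non-Gaussian heavy tails, informative dropout, or correlated left/right
hemispheres. Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness of any
segmentation method on real images.

## Numerical choices and degenerate inputs

- Sample SDs use the n−1 denominator everywhere; a single value has no SD
  and is rejected.
- ICC with MS_E = 0 returns the degenerate point estimate/interval 1; zero
  total variance is an error (ICC undefined).
- Identical paired samples return p = 1 ("no evidence of difference")
  rather than an error; constant samples are errors for the KS, F and
  correlation procedures, whose statistics are undefined.
- Exact-Wilcoxon counts are integers below 2²⁵ and exact in float64.
- `log_posterior` returns −inf (rejected region) for non-positive scales
  instead of raising, so samplers can evaluate it freely.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical configs produce
  bit-identical tables, draws and reports. Pipeline reports echo the
  configuration, seed and package version.
- Test and acceptance problem sizes (200 ICC replicates, 1000 null
  replicates for calibration, 50 BLME replicates at 500 + 500 draws) were
  chosen to keep Monte-Carlo error comfortably below the asserted
  tolerances while the full suite runs in a couple of minutes on one CPU.

## Limitations

- The BLME model has no covariates (age, diagnosis, scanner): time from
  baseline is the only predictor, matching the evaluation protocol; group
  modelling is out of scope.
- Fisher's z-test treats the compared correlations as independent although
  they share the manual volumes; a dependent-correlation test (Steiger /
  Williams) would be the extension point.
- The CI-overlap rule is a conservative heuristic, not a calibrated test;
  its type-I behavior depends on interval width.
- The consistency ICC ignores absolute agreement; a fixed session offset is
  deliberately invisible to it (use VPD to see it).
- No image I/O, segmentation, Dice or surface-distance metrics: the package
  starts where volume tables exist.
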