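# Methods

This note documents the statistical models the package implements, the
synthetic-data design behind its replication experiments, and the numerical
choices a maintainer should know about.

## The nested count generator

A sampling unit is 100 sweeps (sweep net, squaring) or 1.5 row-m of plants
shaken onto a drop cloth (bloom). Units sit in quadrants (4 per field),
fields in agricultural districts, districts in states, and each field is
surveyed in one of the study years; sweep sampling contributes one unit per
quadrant, drop-cloth sampling two.

Counts are generated in two layers:

1. **Hierarchy.** Each level `l` carries an independent multiplicative
   lognormal effect `e_l = exp(N(−σ_l²/2, σ_l²))` with `E[e_l] = 1`, so a
   unit's conditional mean is `m = μ · e_year · e_state · e_district ·
   e_field · e_quadrant`. Multiplicative effects keep means positive, which
   an additive ANOVA-scale model cannot.
2. **Unit noise.** Given `m`, the count is negative binomial with variance
   `a·m^b` (Taylor's power law), drawn through its gamma–Poisson mixture;
   when `a·m^b ≤ m` the law crosses the Poisson line (possible for
   `a < 1 < b` at small means) and the draw falls back to Poisson, since a
   negative binomial cannot be underdispersed.

**Matching variance shares.** Users specify the share of total raw-scale
count variance per source. With sequential (top-down) components, level `l`
contributes `μ²·v_l·Π_{k<l}(1+v_k)` where `v_l = exp(σ_l²)−1`, and the
error stratum contributes `E[a·m^b] = a·μ^b·Π(1+v_l)^{b(b−1)/2}`. The σ_l
are solved top-down from the shares. One overall scale remains free: either
the user anchors it with `total_sd` (the default spec anchors at 4.4, the
reported SD of the sweep validation pool), or it is inferred by fixed-point
iteration so the error stratum receives exactly its share. When an anchor
is given the error stratum is whatever the Taylor relation implies, so the
realized error share can deviate from the nominal one; the hierarchy shares
are honoured exactly in expectation.

**What the generator does not emulate.** Within-quadrant spatial
autocorrelation between transects, observer effects, zero-inflation beyond
the negative binomial, and year-by-landscape interactions. Passing tests
therefore demonstrate internal consistency of estimator and generator at
the study's scale, not robustness of the estimators to those features of
real scouting data.

## Calibration of the Taylor-law replication

The power law is refit the way field studies fit it: per-field sample
means and variances (4 units per field for sweep, 8 for drop) and OLS of
log10(variance) on log10(mean), groups with zero mean or variance
excluded. A variance estimated from four counts is extremely noisy, and the
log of a noisy variance is biased low (Jensen); the exclusion rule and
errors-in-variables in the regressor add further distortion. Generating
data whose true group variance is exactly `a·m^b` and refitting therefore
*does not* return `(a, b)`: at the sweep design the median refit of
(0.95, 1.11) is roughly (0.83, 0.97).

Because the package's replication experiments are defined as "data that
reproduce the study's fitted law under the study's estimator",
`calibrate_taylor_generator` inverts this map by Monte Carlo: a damped
fixed-point iteration (common random numbers, 200 replicates per
evaluation) finds the generating pair whose median refit equals the nominal
pair. For sweep-net conditions (mean 2.9, SD 4.4, 94 fields × 4 units) the
calibrated generating pair is ≈ (1.14, 1.25); for drop-cloth conditions
(mean 0.7, SD 1.3, 66 fields × 8 units) the refit exponent saturates —
most fields have means below one insect per unit, where excluded
zero-variance groups pin the fit toward the Poisson line — so the
generating exponent is capped at 1.85 and the centred refit lands about 4%
below the nominal `b`. That residual gap is a property of the estimator at
low density, not of the optimizer.

A related caveat: the *replicate-to-replicate* spread of the refit
(SD ≈ 0.07–0.10 for `a`) is larger than the published CI half-widths
(0.03–0.08), because one simulated survey carries less information about
the law than the original data's leverage implies. Centred medians are
therefore the meaningful recovery statement; per-replicate containment in
the published CIs cannot reach high rates for any generator.

## Variance components and the CV test

`fit_nested_vca` implements Henderson Method I: sequential sums of squares
in nesting order (year, state, district-in-state, field, quadrant-in-field)
via incremental orthonormal bases, with expected values
`E[SS_k] = Σ_l σ_l²·‖U_kᵀZ_l‖²_F + σ_e²·df_k` equated to observations and
solved by least squares. On balanced designs this reproduces the classical
expected-mean-squares solution exactly (verified against hand ANOVA).
Negative solutions are truncated to zero before percent variation is
computed. Sources whose dummies add no rank (one year sampled; one unit per
quadrant leaving no residual replication) get 0 df and a zero component —
the drop-cloth design with a single unit per quadrant confounds quadrant
and error, which is why share-recovery experiments use two units per
quadrant. Per-source CV is reported as `sqrt(vc)/mean` (a ratio, the
convention of the study's tables, not ×100). Percent variation is a ratio
of skewed estimates, so with lognormal effects its expectation sits a few
points below the generating share for the largest components; the ±10-point
recovery tolerance used in tests reflects that.

The CV comparison is the Feltz–Miller asymptotic test: with `c_i` the
sample CVs and ν_i = n_i − 1,
`χ² = Σ ν_i (c_i − c_pool)² / (c_pool²(0.5 + c_pool²))` on k−1 df.

## Sampling plans

Green's fixed-precision sample size is `N = a·m^(b−2)/D²` with `D` the
target SE/mean (default 0.25). Its sequential form stops after `n` units
once the cumulative count reaches `T_n = (D²·n^(b−1)/a)^(1/(b−2))`;
solving `T_n/n = m` recovers `N` exactly (tested on a parameter grid).
`b = 2` is degenerate (the plan is mean-free) and raises.

Resampling validation draws observed units with replacement, accumulating
`(n, T)` until the stop rule fires, with the rule first evaluated at
`n_min_start = 3` units so a single lucky draw cannot end sampling; the cap
for all-zero pools is 1000 units with a warning. Two properties matter for
interpretation: terminal means are biased upward (sampling stops
preferentially after high draws), and consequently the average terminal
sample size exceeds the plug-in `N` at the pool mean — on a sweep-like pool
(mean 2.9, SD 4.4) the plug-in is ≈ 6 units while the resampled average is
≈ 7–8, matching the reported behaviour of the procedure.

## Threshold agreement

Quadrant estimates are unit means per quadrant; the field estimate is the
mean of its quadrant estimates (option: mean over raw units). "At or above
threshold" counts as above — the conservative treat-on-tie convention. The
2×2 quadrant-call × field-call table is tested by a plain chi-square
independence test (no continuity correction); degenerate tables (an empty
margin) report χ²=0, p=1. Single-quadrant inadequacy is the share of
below-threshold quadrants within fields called at/above threshold, and is
flagged undefined when no field is hot.

## The injury model

Retained squares `r` (of 25 inspected first-position squares per quadrant)
given paired density `d`: `r ~ Poisson(exp(β₀ + β₁·d + b_field + b_quad))`
with independent Gaussian intercepts per field and per quadrant-in-field.
The response is the retained *count* with the 25 positions as a known
denominator for the derived percent scale; the generator truncates draws at
the number of positions, which shaves the mean slightly below the
log-linear rate at high retention (quantified in tests against the
truncated-Poisson expectation). A binomial model would arguably be more
natural but is out of scope; the Poisson choice mirrors the analysis this
package replicates.

Random effects are integrated by a Laplace approximation: an inner Newton
solve of the concave penalized likelihood over the intercepts, an outer
quasi-Newton search over (β₀, β₁, log σ_field, log σ_quad), slope
inference by likelihood-ratio χ² against the β₁ = 0 submodel, and a
slope SE from the inverse numeric Hessian of the marginal deviance. SDs
estimated below 1e-4 are reported as 0 (boundary fits are legitimate, not
errors). The Laplace fit collapses to an ordinary Poisson GLM when the
generating SDs are zero (tested against statsmodels within 1e-3 on the
slope).

## The spatial landscape model

Per field visit `i`: `Y_i ~ Poisson(μ_i)`,
`log μ_i = α₀ + log q_i + X_iβ + W(s_i) + u_stage(i)`, with `q_i` the
number of quadrants sampled (effort offset), `X_i` the proportions of
agriculture, corn, cotton, forest, peanuts, soybeans and double-crop
wheat/soybeans within the 0.5 km buffer (wheat is excluded by default,
matching the covariate set retained after model selection), `W` a Matérn
ν=1 field over planar km coordinates (κ = √8/ρ, so correlation ≈ 0.14 at
distance ρ), shared by both visits to a field, and `u` a growth-stage
effect.

At survey sizes (n ≈ 120–420 rows) the field is represented exactly on the
observed locations — no mesh or Markov approximation is needed. Inference
is INLA-style: Gaussian priors N(0, 100²) on α₀ and β; for each node of a
grid over (σ_w², ρ, τ) — log-spaced σ_w² ∈ [1e-3, 10], ρ ∈ [1, 100] km,
τ ∈ {0.1, 0.5, 2} with a half-Normal(0,5) prior — the latent vector is
maximized by damped Newton (backtracking line search, ridge retries,
jitter 1e-8·σ² on the covariance diagonal) and approximated by the
Gaussian at the mode; nodes are mixed by approximate marginal likelihood ×
prior. Posterior summaries are moment-matched Gaussians of that mixture;
"significant" means the 95% interval excludes zero. The intervals are
treated as credible intervals. Doubling all offsets shifts α₀ (plus the
weakly identified stage effects) by −log 2 and leaves slopes unchanged
(tested). Cross-validation splits rows 80/20, refits on the training rows,
and predicts test rows with the fitted `W` (kriged via the conditional
Gaussian mean at the max-weight hyperparameters for unseen fields), then
regresses observed on predicted counts.

The landscape generator draws buffer compositions from a Dirichlet over a
9-class cover split whose means describe a southeastern row-crop mosaic
(cotton 0.20, forest 0.30, soybeans 0.12, corn 0.08, …, concentration 8);
"agriculture" is the sum of cultivated classes including an unnamed
residual class, so it is correlated with — but never collinear to — the
named subclasses. Generating defaults for coefficients are the study's
fitted values; the spatial field defaults (σ_w² = 0.5, ρ = 30 km, stage SD
0.3) are unreported in the source analysis and were chosen once as
plausible for a 100 × 100 km window with tens-of-km spatial structure.

## Problem sizes and reproducibility

Replication experiments run at the study's scale: 94 fields × 4 sweep
units and 66 fields × 8 drop units per replicate (100 replicates) for the
power law; pools of 330 and 439 units with 500 resampling simulations for
the plans; 50 replicates of 200 fields (400 rows) for the landscape model.
Every stochastic routine takes an explicit integer seed; a single pipeline
seed fans out to stage-level child seeds via `SeedSequence`, so stages
re-run in isolation reproduce byte-identical artifacts.
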