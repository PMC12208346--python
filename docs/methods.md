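# Methods

## Compositional representation

A night is the 4-part composition x = (TWT, light, SWS, REM) with closed
total equal to time in bed (TIB). Only relative information is modelled:
internally compositions are carried as proportions with TIB retained
separately, and minutes are reconstructed on demand, which makes
scale-invariance explicit.

Isometric log-ratio coordinates are z = V ln x, with V the (D−1)×D
orthonormal contrast matrix of a sequential binary partition: a row that
splits r "positive" parts from s "negative" parts carries +sqrt(s/(r(r+s)))
and −sqrt(r/(s(r+s))). The default SBP is wake vs sleep, then light vs
deep (SWS+REM), then SWS vs REM — an interpretable hierarchy; because all
downstream estimates are invariant to the SBP (tested analytically and
under MCMC refits), the choice is presentational and configurable.

Zeros (possible for SWS/REM on a scored night) are replaced
multiplicatively: each zero part is set to δ = 0.5 min — half a plausible
1-minute scoring resolution — and the observed parts are scaled down so the
night total is preserved, keeping their ratios intact. δ is configurable.

## Between/within decomposition

With nightly coordinates z_ij (person i, night j), b_i is the ilr of the
person's geometric-mean composition (equivalently the arithmetic mean of
their z_ij) and w_ij = z_ij − b_i. The decomposition is exact and the
within-person deviations average to zero by construction. The grand
reference composition used for prediction is the closed geometric mean over
persons of the person means (equal person weighting; a pooled-nights
variant is available), scaled to the mean TIB. Nights with any missing
stage are excluded listwise; imputation of multilevel compositions is out
of scope.

## Outcome models

For each affect domain y (average of 1–5 items; high/low arousal ×
positive/negative), four nested Gaussian mixed models:

    y_ij = x_ij' β + z_ij' u_i + ε_ij,  ε ~ N(0, σ²),  u_i ~ N(0, Σ_u)

- a: covariates only; random intercept (q = 1).
- b: a + the three between-person coordinates b_i.
- c: a + the three within-person coordinates w_ij, with correlated random
  slopes on them (q = 4, unstructured Σ_u).
- d: b and c combined, variant-c random structure.

Covariates: TIB, matched previous-night pre-sleep affect, weekend
indicator, circadian misalignment (composite phase deviation, consumed as a
ready-made value), and baseline age, gender, ethnicity, subjective social
status, BMI. Numeric covariates are mean-centred; categoricals enter as
dummies against the most frequent level. An optional TIB × composition
interaction set is available as a model variant (the moderation test).
Affect is treated as continuous with identity link so substitution effects
are additive point differences on the 1–5 scale; ordinal/beta likelihoods
and night-to-night autoregression are non-goals.

### Priors

Weakly informative and scale-adapted: coefficient j gets
Normal(0, 5·sd(y)/sd(x_j)); the intercept Normal(median(y), 5·sd(y)); the
residual SD a half-t(3) with scale 2.5·sd(y) (via inverse-gamma parameter
expansion). The random-effect covariance is parametrised by its Cholesky
factor Σ_u = diag(ξ) L L' diag(ξ) with independent Normal(0, 2.5·sd(y))
entries in L and Normal(0,1) redundant row scales ξ, giving heavy-tailed
half-normal-product marginals on the SDs and near-uniform correlations.
This normal-on-factor family was chosen over half-t + LKJ because every
conditional stays conjugate; it is equally vague at these scales. All
scales are configurable.

### Sampler

A blocked Gibbs sampler, fully vectorised over persons:

1. β from its partially collapsed conditional with u integrated out
   (per-person Woodbury identities) — decouples person-level covariates
   from person intercepts;
2. non-centred person effects η_i ~ conditional normal, batched;
3. the entries of L and the row scales ξ, each linear in the likelihood
   given η, from joint conjugate normals;
4. a Metropolis move on the row scales of L against the
   random-effects-marginalised likelihood (adaptive log-scale random walk,
   tuned during warmup) — full-posterior-width moves for well-identified
   scales;
5. σ² and its auxiliary from inverse-gammas.

The combination addresses both classic failure modes: centred samplers
have absorbing near-zero states for weakly identified slope SDs, and
non-centred ones crawl for well-identified intercept SDs. Posterior means
agree with the statsmodels MixedLM maximum-likelihood fit to a few
hundredths of a posterior SD on 300×10 data (tested), and chains are
bit-reproducible given (spec, data, seed).

Desk defaults are 4 chains × (500 warmup + 500 kept); study-scale settings
(8 × 5000 kept = 40 000 draws) are one config away. Convergence is gated
at R-hat < 1.05 and ESS > 400 on all fixed effects, random-effect SDs and
σ²; a fit failing the gate is returned with `converged=False` and a logged
warning, never silently. At desk-scale draw counts the random-effect SDs
are the ESS bottleneck (~150–450), so the gate is sometimes honestly
missed while fixed-effect ESS exceeds 1500; the gate passes at
study-scale settings.

### Derived quantities

Pointwise log-likelihood is the conditional Gaussian density (person
effects included), matching the fitted likelihood. Bayesian R² per draw is
var(pred)/(var(pred)+σ²), with fixed-effects-only predictions (marginal) or
including person effects (conditional); reported as posterior mean and
equal-tailed 95% CI. The unadjusted marginal R² is noticeably inflated in
small samples by chance association of the ~11 person-level covariates —
visible in the null-data tests and consistent with covariate-only models
reporting marginal R² ≈ 0.15 at ~100 persons.

## Model comparison

PSIS-LOO: per observation, importance ratios 1/p(y_i|θ_s) are
Pareto-smoothed (arviz's generalised-Pareto tail fit on the largest
ratios); elpd_i is the log smoothed-weighted mean predictive density, with
per-observation Pareto k reported and a logged warning above k = 0.7.
Δelpd is each model's elpd minus the best model's; models with Δ > −2 are
"strong", Δ < −10 "poor". Stacking maximises the pooled log score of the
weighted predictive mixture over the simplex — a convex problem solved
deterministically (softmax parametrisation, fixed uniform start, tiny
ridge), so exchangeable models split weight evenly. A squared-error
variant (weights minimising LOO MSE of predictive means) is available; the
log score is the default as the standard stacking objective for predictive
distributions.

## Substitution analysis

For reallocation spec (level, donor, recipient, t): the donor loses and
the recipient gains t minutes at the reference composition, TIB fixed.
Between level: the person-mean coordinate moves from b = ilr(ref) to
b' = ilr(ref'), with w = 0. Within level: b stays at the reference and
w' = ilr(ref') − ilr(ref). The per-draw difference in expected affect is
taken through the fixed effects (population level — random effects at
their zero mean; estimates describe a typical person); covariates sit at
their reference (means / reference levels), and cancel in the difference.
Summaries: posterior mean, equal-tailed 95% CI, significance iff the CI
excludes zero, and the mean standardised by the observed outcome SD
(model-based level-specific SDs selectable — no single divisor is
canonical). The grid is integer minutes 1…60 in both directions for all
ordered stage pairs; infeasible points (a stage exhausted) are skipped
with a log entry, never clamped. Because minutes map non-linearly into
ilr space, +t and −t effects are genuinely asymmetric even under a linear
model — the reason both directions are reported.

## Synthetic-data generator

Person-mean ilr coordinates are multivariate normal around the ilr of the
target geometric-mean proportions (0.13, 0.43, 0.21, 0.23); daily
deviations are multivariate normal around zero (logistic-normal
compositions — matching the analysis model's geometry and making the true
substitution curves analytic, rather than Dirichlet). Total coordinate
variances (0.23, 0.10, 0.13) reflect nightly stage-minute spreads with
CVs of 0.3–0.6, split 35% between / 65% within persons to land composition
ICCs in 0.29–0.40. TIB is truncated-normal(448.66, 95.47, floor 180 min).
Affect is linear in (b, w) with person random intercepts (SD 0.48), random
within-coordinate slopes (SD 0.06), residual SD 0.38 — affect ICCs around
0.55–0.67 — plus pre-sleep affect, weekend and circadian covariate
effects, clipped to [1, 5] (defaults keep clipping under ~1%). Sleep
nights and morning-affect reports are masked completely at random at 4%
and 19%; the emulated design is complete-case, so MAR machinery is
unnecessary for testing. Persons enter on random weekdays so the weekend
indicator varies even in short studies.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: night-to-night dependence (REM rebound),
floor effects of negative affect (real negative-affect means sit near the
scale floor; synthetic intercepts are kept central to avoid clipping),
informative missingness, measurement error in staging, and intra-night
stage sequencing.

ICCs are estimated by method-of-moments one-way ANOVA with the
unbalanced-design group-size correction, validated against a known
two-level simulation; composition ICCs are computed on the ilr
coordinates.

## Pipeline

Per outcome: decompose → fit a–d → compare → post-hoc substitution only at
levels supported by the improvement criterion — some model containing that
level's terms has stacking weight > 0 (numerically, > 10⁻³, configurable)
and Δelpd > −2. Where several qualifying models contain a level, the one
with the larger stacking weight supplies the substitution posterior. All
stage seeds derive from the pipeline seed; reruns are bit-identical.
Reports are CSV tables (model comparison with weights, Δelpd, R²;
substitution grids) plus a text summary with "unstandardised, standardised
[CI]" cells.

## Problem sizes in tests

The test suite exercises the pipeline at 30–100 persons × 5–14 nights with
4 × (500 + 500) draws, and the generator's calibration checks at 500
persons; parameter-recovery uses 10 replicates of 60 × 10. These sizes
give stable verdicts for every property tested while keeping the full
suite under a few minutes.

## Known limitations

- Gaussian likelihood for a bounded 1–5 outcome; defensible for mean
  differences but wrong in the tails, especially near the negative-affect
  floor.
- Unadjusted Bayesian R² inflates in small samples (documented above).
- The random-effect prior is vague on SD scales; with very few persons the
  slope-SD posteriors are prior-sensitive.
- PSIS-LOO uses the conditional likelihood, so it measures
  within-person out-of-sample prediction; between-person covariates earn
  little elpd when persons contribute many nights — model-comparison
  verdicts about between-level terms are correspondingly conservative.
- One-to-many reallocations and covariate moderation of substitution
  effects are not implemented.
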