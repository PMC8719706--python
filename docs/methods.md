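# Methods

This note documents the statistical models, the numerical choices, and
the design decisions behind `heartscore`, in the order a reader meets
them in the pipeline.

## Instrument and scoring

The instrument is configuration-driven (JSON): five subscales, 42 items,
6-point response codes. The full item text bank is not public; the
shipped default uses placeholder identifiers (`tv_01` … `hpr_05`) with
the published exemplar texts attached where available. Whether any items
were reverse-scored before summation is not documented for the original
tool; the published score conventions (high PS = supportive alongside
negatively worded PS exemplars) imply some orientation rule, so the
default configuration marks the negatively worded PS exemplar as
reversed (`x → 7 − x`) and records this as an assumption. Orientation is
an involution, so applying it twice is a no-op.

Scoring follows the mean-of-available imputation rule: with `m` of `k`
items missing and available sum `s`, the score is `(k/(k−m))·s`. The
original description is silent on how many missing items still permit a
score; the default requires ≥ 50 % of the subscale's items
(configurable via `min_present_fraction`) because mean imputation from
fewer than half the items is unstable. Scores are kept at full precision
internally; reports display one decimal.

Visits are mapped to a linear index: baseline 0, month 3 → 1, month 6
→ 2. The month-1 booster (administered only to participants reporting a
new partner) is stored at 0.33 and excluded from growth models by
default, since it would distort the regular time grid.

## Benchmark classification and triage

Classification is `z = (score − μ)/σ` against the formative-survey
benchmarks (shipped in `data/benchmarks.json` with provenance), with
"one or more standard deviations" read as boundary-inclusive
(`z ≤ −1`, `z ≥ +1`). A 1e−9 guard keeps scores computed exactly at the
threshold from landing on the wrong side in floating point.

The module rule table (configuration, not hard-coded): C on any risk
flag (low PS, high PAC, high PR), B on non-full disclosure, A when
nothing else triggers. TV and HPR are classified and reported but never
flagged — no action is attached to them. At follow-up visits
classification is computed for monitoring but module recommendation is
suppressed by default (a flag re-enables it), mirroring the pilot's use
of follow-up administrations. Counselor overrides never mutate the
rule-based recommendation; they are applied on top and retained in the
audit trail with their note.

## Reliability coefficients

Raw Cronbach's alpha uses item variances with the n−1 denominator;
standardized alpha uses the mean off-diagonal correlation; Guttman's λ₆
uses squared multiple correlations from the inverse correlation matrix
(`smc_j = 1 − 1/(R⁻¹)_jj`). Reliability is computed on
listwise-complete item matrices by default — the coefficients describe
the instrument as answered, not the imputed data — with a flag to use
row-mean-imputed matrices instead. Subscale-score correlations use
pairwise-complete observations. Degenerate inputs (zero total variance,
singular correlation matrices, fewer than 3 respondents or 2 items) are
rejected with explicit errors rather than returning NaN.

## Group comparisons and logistic models

Welch's t statistic with Satterthwaite degrees of freedom; one-sided
alternatives are configured per grouping/subscale from the instrument's
construct hypotheses (PS higher where relationships are supportive; PAC
and PR higher where they are not; TV always two-sided). When both
samples are constant the test returns p = 1 by convention with a
warning.

Logistic regression is iteratively reweighted least squares on the
binomial log-likelihood with step-halving, so the deviance is monotone
non-increasing; convergence is a relative deviance change below 1e−8
(max 50 iterations). Separation is detected (any standardized |β| > 10),
reported via `converged=False` and a warning, and deliberately not
repaired — no Firth correction. Standard errors come from the observed
information; odds-ratio SEs use the delta method (`SE_OR = OR·SE_β`),
with log-scale SEs retained. Predictors in `or_table` are z-scored on
the analysis sample (n−1 SD); significance stars at 0.1/0.05/0.01 with
no multiple-testing adjustment, matching the reporting convention of the
validation tables this mirrors.

## Growth models

The default model per subscale is the minimal specification consistent
with four linear group trajectories (baseline IPV × IPV-module receipt):
fixed effects intercept, visit, both group indicators, and both
visit-interactions; a participant random intercept `u_i ~ N(0, τ²)`; and
residual `ε ~ N(0, σ²)`. Estimation is maximum likelihood (not REML,
which would shift the variance components slightly) via EM with the
random intercepts as missing data. The marginal log-likelihood is
evaluated with the Woodbury identity, asserted non-decreasing at every
iteration, and converged at a relative change below 1e−6 (max 500
iterations). Because EM only approaches the τ² = 0 boundary
geometrically, the boundary candidate (plain OLS) is evaluated at
convergence and adopted whenever it is at least as likely. With one
observation per participant τ² and σ² are not separately identified;
the fit detects this and falls back to OLS with a warning. Fixed-effect
covariance uses the GLS information at the final variance estimates.

## Synthetic cohort generator

The generator emulates the study conditions the analyses assume, so the
whole pipeline is testable without the (unavailable) participant data.

**Measurement model.** Each subscale is a set of parallel items: one
latent factor, equal loadings, equal noise. Only alphas are published,
not loadings, so a parallel model is the most parsimonious choice; the
inter-item correlation implied by a target alpha comes from inverting
Spearman–Brown, `ρ = α/(k − α(k−1))`.

**Discretization.** Continuous item values are discretized by rounding
to the nearest code and clipping to [1, 6] — equally spaced thresholds.
Clipping near the floor (PAC, PR) or ceiling (PS, HPR) both shifts
means and shrinks variances and covariances, so the continuous location
μ, scale s, and pre-discretization inter-item correlation ρ are
*moment-matched*: a numerical solve (normal-CDF cell probabilities plus
61-node Gauss–Hermite quadrature over the common factor) picks (μ, s, ρ)
such that the discretized items reproduce the target item mean, the
target summed-score SD, and the target alpha in expectation. A simpler
center-only calibration was evaluated first and rejected: with the
pilot's skewed score distributions it misses summed-score SDs by several
points and alphas by more than 0.05.

**Correlation targets.** The configured 5×5 matrix is on the *observed
score* scale — what a correlation matrix of scored data shows. Observed
correlations are attenuated relative to the latent factors by
measurement noise and by the nonlinear discretization; for latent
correlation L the cross-scale item covariance is
`Σₙ n!·c_nᴬ·c_nᴮ·Lⁿ` over the Hermite coefficients of each scale's
conditional item mean, and the generator solves this per pair for the
latent L that realizes the observed target. Only two off-diagonal cells
are published (PAC–PS −0.63, PAC–PR 0.52 in the pilot); the remaining
defaults are modeller's choices consistent with the reported qualitative
pattern and with positive definiteness of the implied latent matrix —
the strong PS/PAC/PR triangle leaves the TV row little room, so TV–PAC
and TV–PR default to near zero. Observed targets whose implied latent
matrix is not positive definite are rejected at validation.

**Outcomes.** Binary IPV and disclosure are Bernoulli draws from
logistic models on the z-scored latent scores: IPV rises with PAC
(+0.105 per SD, matching the published 11 % adjusted odds increase) and
PR (+0.135) and falls with PS (−0.10), with intercept −1.95 giving
≈ 12 % prevalence; full disclosure mirrors this (PS +0.058, PR −0.105,
intercept 0.5 for ≈ 62 % prevalence). Auxiliary covariates (cohabiting
39 %, age ≤ 25 26 %, new partner 8 %) are independent Bernoulli draws at
the pilot's reported rates. Module assignment is not a simulation input:
it is derived by running the triage engine on the scored baseline
responses together with the drawn disclosure status.

**Longitudinal structure.** The baseline latent score carries the
persistent between-participant differences (it *is* the random
intercept); follow-up latent scores add per-subscale visit effects
(defaults: TV −1.5, PS +1.5, PAC −1.0, PR −0.8, HPR +0.3 per visit
unit, consistent with the reported directions of change), slope
modifiers for baseline IPV and for IPV-module receipt (PAC −1.5 per
visit for module C), and fresh within-participant noise. Item responses
are regenerated at every visit: measurement error is per
administration, so observed scores fluctuate around the latent
trajectory even when the trajectory itself is flat. The
"zero-effects/zero-noise ⇒ frozen trajectory" property therefore holds
on the ground-truth latent scores, not on the re-measured item
responses.

**What the generator does not emulate.** MCAR missingness only (nothing
is reported about the real missingness mechanism); no informative
dropout; no counselor discretion in module assignment (the real pilot
offered module C more liberally than the strict rule); no new-partner
dynamics in the trajectories; item-level behavior beyond the parallel
model (no difficulty/discrimination structure, no response styles).
Passing calibration tests shows the *analytic machinery* recovers known
structure — it says nothing about how the real instrument behaves in a
new population.

## Problem sizes

Calibration checks use single cohorts of n = 10,000 (Monte-Carlo error
on a mean of SD-12 scores ≈ 0.12 points, comfortably inside the ±0.5
calibration band). Adjusted odds-ratio recovery averages 40 cohorts of
n = 10,000 because the strong PS/PAC/PR collinearity inflates the
adjusted-coefficient variance roughly four-fold. Growth-model coverage
uses 200 replicates at the pilot's size (n = 95, 3 visits); fixed-effect
recovery uses one cohort of n = 500. All simulations are seeded and
bit-reproducible.

## Known limitations

* The reliability battery assumes essentially tau-equivalent items;
  alpha understates reliability for congeneric scales.
* λ₆ requires an invertible item correlation matrix; perfectly
  collinear items must be dropped first.
* The EM fit supports a random intercept only (a random slope is out of
  scope); ML variance components are biased low in small samples
  relative to REML.
* Separation in logistic models is flagged, not repaired.
* The generator's unpublished correlation cells are assumptions; any
  analysis sensitive to them should treat those cells as free
  parameters, not facts.
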