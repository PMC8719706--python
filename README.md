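# heartscore

Scoring, benchmark triage, and validation analytics for the **HEART**
(HEAlthy Relationship Assessment Tool) — a 42-item, five-subscale
questionnaire administered by lay counselors to characterize a woman's
primary partner relationship in HIV-prevention counseling programs.

The five subscales, each a sum of 6-point Likert items (1 = strongly
disagree … 6 = strongly agree):

| Code | Subscale | Items | Score range | Risk direction |
|------|----------|-------|-------------|----------------|
| TV   | Traditional Values | 13 | 13–78 | — |
| PS   | Partner Support | 10 | 10–60 | low |
| PAC  | Partner Abuse & Control | 9 | 9–54 | high |
| PR   | Partner Resistance to HIV Prevention | 5 | 5–30 | high |
| HPR  | HIV Prevention Readiness | 5 | 5–30 | — |

The package is for biostatisticians and implementation researchers who
need to (a) run the operational pipeline — score responses, compare them
to reference benchmarks, and produce counselor-facing triage reports —
and (b) reproduce the instrument's psychometric validation battery on
data with the same statistical structure.

## What it computes

**Scoring.** Item responses within each subscale are summed after
replacing any missing response by the mean of the available responses in
that subscale: with *m* of *k* items missing and *s* the available sum,
the score is *(k/(k−m))·s*. A subscale is scored only when at least half
its items were answered.

**Triage.** Each score is compared to a benchmark mean/SD from the
instrument's formative development survey: *z = (score − μ)/σ*, with
*z ≤ −1* "low" and *z ≥ +1* "high" (boundaries inclusive). Low PS or
high PAC/PR places the participant in the risk zone, which triggers a
recommendation for the IPV-prevention counseling module (C); non-full
disclosure triggers the disclosure module (B); the partner-communication
module (A) is the default. Counselor overrides are applied on top of the
rule-based recommendation and always audited.

**Validation battery.** Cronbach's raw alpha *k/(k−1)·(1 − Σsᵢ²/s_T²)*,
standardized alpha *k·r̄/(1+(k−1)·r̄)*, Guttman's λ₆ from squared
multiple correlations, pairwise-complete subscale correlation matrices
and two-sample comparison; Welch unequal-variance *t* tests with
Satterthwaite degrees of freedom (one-sided where hypothesized);
logistic regression by iteratively reweighted least squares, reported as
odds ratios per SD with delta-method standard errors; and
random-intercept growth models *Y_ij = x_ijᵀβ + u_i + ε_ij* fit by EM
maximum likelihood.

**Synthetic cohorts.** No participant-level data from the original
studies is available, so `heartscore.synthetic` generates cohorts
calibrated to the published summary statistics — subscale means/SDs,
alphas (via the Spearman–Brown relation *α = kρ/(1+(k−1)ρ)* and a
moment-matched 6-point discretization), the subscale correlation
structure, outcome models linking IPV and disclosure to the scores, and
three-visit trajectories with counseling-module effects. See
`docs/methods.md` for the generator's model and its limits.

## Worked example

Simulate a small cohort, score it, and produce triage reports:

```sh
heart simulate --seed 42 --n 6 --baseline-only --out-dir sim
heart score sim/responses.csv --out scores.csv
heart triage sim/responses.csv --covariates sim/covariates.csv --out-dir reports
```

`scores.csv` (subscale columns shown):

```
participant_id,visit,TV,PS,PAC,PR,HPR
P0001,baseline,24.916666666666664,49.0,20.0,5.0,30.0
P0002,baseline,35.0,49.0,9.0,5.0,27.0
...
P0006,baseline,26.0,45.0,14.0,22.0,30.0
```

P0001's TV score is fractional because one missing TV response was
imputed with the mean of the twelve answered items. `reports/P0006_baseline.md`:

```
# HEART report — participant P0006, visit baseline

| Subscale | Score | z | Level | Risk flag |
|---|---|---|---|---|
| TV | 26.0 | -0.41 | medium |  |
| PS | 45.0 | -0.12 | medium |  |
| PAC | 14.0 | -0.58 | medium |  |
| PR | 22.0 | +1.77 | high | YES |
| HPR | 30.0 | +0.73 | medium |  |

Risk zone: PR
Recommended modules: C
```

P0006's Partner Resistance score of 22 sits 1.77 SD above the survey
benchmark (10.5, SD 6.5), so PR is flagged and the IPV-prevention module
is recommended. The analytic commands follow the same pattern:
`heart reliability` (alpha/λ₆ table), `heart compare` (Welch group
comparisons), `heart logit` (odds-ratio tables), `heart growth`
(per-subscale growth model and predicted group trajectories).

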