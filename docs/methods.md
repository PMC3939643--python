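# Methods

## Statistical model

Each trial arm contributes a mean change from baseline on the IIEF-EF
scale, y_i, with within-study sampling variance v_i = sd_i²/n_i, where
sd_i is the SD of the individual change scores and n_i the analyzed sample
size. Arms are analyzed as single-group effect sizes: placebo and
intervention groups are pooled separately, so the quantities of interest
are within-arm responses, not treatment contrasts. (The multivariate model
for intervention effects re-introduces the placebo-arm response as a
covariate to partially account for randomization; see below.)

Pooling uses generic inverse variance under an additive random-effects
model, y_i ~ N(θ_i, v_i), θ_i ~ N(μ, τ²). τ² is estimated by
DerSimonian–Laird moments: with fixed-effect weights w_i = 1/v_i,
Q = Σ w_i (y_i − μ̂_FE)², and

    τ̂² = max(0, (Q − (k−1)) / (Σw_i − Σw_i²/Σw_i)).

Random-effects weights are w*_i = 1/(v_i + τ̂²); μ̂ = Σw*y/Σw*,
se(μ̂) = (Σw*)^(−1/2), 95% CI = μ̂ ± 1.96·se. I² = max(0, 100·(Q−df)/Q),
and Q is referred to χ²(k−1). With a single study the random-effects call
degrades to the fixed-effect identity with a warning. These are the
conventions of mainstream meta-analysis software (RevMan-style): no
Knapp–Hartung adjustment, normal multiplier 1.96 throughout.

### Blinding classification and stratum differences

A trial's blinding status derives from the four blinding-related Cochrane
risk-of-bias domains (allocation concealment; blinding of participant,
caregiver and outcome assessor), each judged low / unclear / high:

* **adequate** — all four domains low;
* **inadequate** — at least one domain high, or all four unclear;
* **indeterminate** — any other mix of low and unclear.

The rules are deliberately non-exhaustive in the middle: of the 81
possible level vectors, 1 is adequate, 66 inadequate and 14 indeterminate;
indeterminate trials are excluded from the primary comparison (they
dominate real data sets, which is precisely the reporting problem this
kind of analysis documents).

Strata are pooled separately and compared on the pooled means:
d = μ̂_a − μ̂_b, se_d = √(se_a² + se_b²), CI d ± 1.96·se_d, z = d/se_d with
a two-sided normal p. The *nocebo effect* is d for placebo arms
(adequate − inadequate); the *enhanced placebo effect* is d for
intervention arms. The relative effect is 100·d/μ̂_a (reference: the
adequately blinded stratum), reported rounded to integer percent and
undefined when |μ̂_a| < 1e−8. Between-stratum heterogeneity is
Q_between = Σ_j w_j (μ̂_j − μ̄)² with w_j = 1/se_j² over the two strata
(1 df); with two strata z² = Q_between identically. Because published
tables are ambiguous about whether their heterogeneity column refers to
the between-stratum Q or the combined-set total Q, both are emitted
(`q_between`, `q_total`). The test of no difference defaults to the normal
approximation; a Student-t variant with k_a + k_b − 2 df is available
(`use_t`) since the appropriate df for the historical analyses is not
recoverable.

The per-domain rows group trials low vs unclear-or-high on that single
domain; empty strata yield a flagged non-estimable row without failing the
remaining rows.

### SD imputation

Missing change-score SDs are reconstructed in a fixed precedence order of
ascending information loss: reported SD; SD = SE·√n; SE = CI width/(2·1.96)
then as SE; SE = |Δ|/|t| then as SE; t from the inverse central t at the
two-sided P with df = n − 1 then as t. The normal multiplier 1.96 for CI
back-calculation and df = n − 1 follow standard systematic-review
handbook practice. P values recorded as inequalities ("<0.05") are
accepted at the bound and flagged conservative in the imputation report.
When only baseline and final SDs exist, no correlation assumption is made
by default — the arm goes to matched substitution (an optional
correlation-based route was considered and rejected as the default because
the change-score correlation is unknowable from the source reports).

Arms that fail the cascade enter **matched-study substitution**: per arm
role, a uniform seeded random subset of the failed arms is selected, capped
so that substituted arms never exceed `max_fraction` (default 0.33) of that
role's analysis set — the cap is the largest m with
m/(n_resolved + m) ≤ max_fraction. Each selected arm receives the SD of
the same-role donor arm minimizing |n_donor − n_recipient| (analyzed n),
ties broken by lexicographically smallest donor trial id. Unselected
failed arms are flagged excluded and drop out of pooling. Sampling is
uniform without stratification; every substitution is recorded
(recipient, donor, SD) in the imputation report. Re-running the cascade on
its retained output is a no-op.

### Risk ratios

For dichotomous outcomes (GEQ responders with randomized denominators —
an ITT convention independent of how source authors defined their ITT
sample — and headache/flushing adverse events),
RR = (a/n1)/(c/n2) with se(log RR) = √(1/a − 1/n1 + 1/c − 1/n2) and a
log-scale 95% CI. A single zero cell adds 0.5 to all four cells of the
2×2 table (Haldane) and flags the result corrected; a double zero is
returned as a flagged non-estimable null.

### Weighted REML meta-regression

Moderator models are y_i = x_i'β + u_i + e_i, u_i ~ N(0, τ²),
e_i ~ N(0, v_i). τ² maximizes the restricted log-likelihood

    ℓ_R(τ²) = −½ [ Σ log(v_i+τ²) + log|X'WX| + Σ w_i r_i² ],

W = diag(1/(v_i+τ²)), r the GLS residuals, via Fisher scoring on the
restricted score with the update projected at zero (convergence tolerance
1e−8 on τ², max 200 iterations; the iterate count and convergence flag are
reported, and non-convergence returns the best iterate flagged). β̂ is GLS
at the converged τ²; coefficient p values use the normal approximation.

Standardized coefficients rescale each non-intercept column and the
outcome to unit variance under the **RE-weighted moments** (weights
1/(v_i + τ̂²)); an unweighted variant is available since the convention of
the historical macro-based analyses is unknowable. Variance explained is
R² = max(0, 100·(1 − τ̂²_res/τ̂²_null)), with τ̂²_null from the
intercept-only REML fit on the same complete-case subset; R² is invariant
to affine rescaling of moderators.

Univariate screens fit one moderator at a time on the records where it is
observed; categorical moderators expand to dummies against a fixed
reference (continent: North America; drug: tadalafil). The multivariate
model is forward-stepwise: starting from intercept-only, the candidate
with the smallest coefficient p enters while p < p_enter (default 0.15, a
deliberately lax criterion; configurable), refitting by REML each step on
the complete cases of the current variable set; categorical blocks enter
on their smallest dummy p. Entry order is recorded. No backward
elimination and no multiplicity correction are applied — screen results
are hypothesis-generating. Intervention-effect models may include the
placebo-arm change (`placebo_effect`) as a covariate.

## Synthetic-data generator

The generator draws trial sets from the analysis model itself plus the
reporting artefacts the imputation stage exists for. True arm means are

    θ_arm,i = μ_arm + δ_arm·1[inadequate] + Σ_m β_m x_m,i + u_i,
    u_i ~ N(0, τ_arm²),

and observed change means are N(θ, sd_i²/n_i) with lognormal sd_i and
per-arm n uniform on `n_range`. Defaults are the study conditions of the
motivating literature: μ_placebo = 1.9, μ_intervention = 9.4 IIEF-EF
points; δ_nocebo = −0.36, δ_enhanced = −1.07 (applied to inadequately
blinded trials only; indeterminate trials get no shift); τ_placebo = 0.8,
τ_intervention = 1.6 (yielding I² in the 60–90% range seen in practice);
5 adequate + 16 inadequate trials; n per arm 25–400; lognormal SD with
meanlog 1.7, sdlog 0.25 (median ≈ 5.5 points, the realistic range for
IIEF-EF change SDs). `moderator_effects` defaults to empty so that the
stated τ values fully determine heterogeneity; moderator-recovery
experiments switch effects on explicitly (e.g. +2.9 points on the placebo
mean for intervention-naive populations, the magnitude of the published
naive-vs-experienced contrast).

Reporting artefacts: with probability 0.3 a trial's SDs are masked in both
arms; a masked trial retains a single statistic with probabilities
SE 0.4 / CI 0.3 / t 0.15 / P 0.15, or nothing with probability 0.15
(exercising matched substitution and exclusion); 30% of trials report only
baseline and final means (exercising change-score derivation); attrition
is Beta(2, 18) (mean ≈ 10% randomized-not-analyzed). Retained statistics
are computed consistently from the generated sd and n, so over-determined
arms are internally consistent. Risk-of-bias vectors are constructed to
match the requested status counts exactly while varying domain patterns.
GEQ responders are binomial with logit rates −0.85 (placebo) and +1.1
(intervention), i.e. ≈30% vs ≈75% responders; AE rates default to
headache 4%/12% and flushing 1.5%/10% (placebo/intervention), typical of
PDE-5 inhibitor safety tables. All randomness flows from a single seed and
a fixed (config, seed) pair regenerates identical CSV bytes.

What the generator does **not** emulate: publication/selection bias,
correlation between blinding status and moderators, crossover carry-over
(crossover trials are generated with the same summary shape and pooled
as reported), skewed or bounded outcome distributions, and trial-level
correlation between placebo and intervention sampling errors. Passing
recovery tests therefore demonstrates the pipeline's internal consistency
under its own assumptions, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* 95% multiplier fixed at 1.96 everywhere (CI back-calculation and CI
  construction) for internal consistency.
* Q = 0 defines I² = 0; k = 1 pooling returns p_Q = 1 on 0 df.
* DL and REML τ̂² are floored at 0; REML collinearity is detected by QR
  with a 1e−10 relative diagonal threshold and reported with the offending
  column names.
* Matched-substitution ties break lexicographically on donor id; selection
  order is independent of input order (failed ids are sorted before the
  seeded draw).
* CSV floats round-trip via `repr`; missing values are empty cells ("NA"
  accepted on read); risk-of-bias levels normalize case- and
  whitespace-insensitively with "unknown" → unclear.
* Trials with underivable change scores or unresolved SDs are excluded
  with per-arm diagnostics rather than silently dropped.

## Problem sizes used in the test and acceptance suites

Oracle-equivalence checks run 100 random instances each for
DerSimonian–Laird pooling and risk ratios (tolerance 1e−6 against longhand
closed-form implementations) and 30 instances for REML τ² (against a
vectorized grid search of the restricted likelihood, step 1e−4 on
[0, 10]). The recovery experiment uses 200 replicates of the default
21-trial configuration; moderator-recovery uses 200 replicates at k = 40.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping the default suite fast.

## Known limitations

* **Small-k coverage.** Normal-theory DerSimonian–Laird intervals
  undercover when a stratum holds few studies and heterogeneity is high:
  with k = 5 and I² ≈ 80% (the default adequate stratum), the 95% CI for
  the pooled mean covers ≈ 90%, and the CI for the between-stratum
  difference ≈ 91–92% — the long-documented behaviour of this estimator,
  which motivated the Knapp–Hartung and related adjustments that the
  RevMan-convention design deliberately omits. The recovery experiment
  reports empirical coverage so this is visible rather than hidden.
* The stepwise screen inherits all the usual caveats of stepwise model
  selection (overfitting, order dependence under collinearity); entry
  order and complete-case counts are reported so results can be audited.
* Published summary tables can embed rounding: differences recomputed from
  printed stratum means (e.g. 1.92 − 1.56 = 0.36) need not equal the
  table's own printed difference computed from unrounded internals.
* Crossover trials are taken at their reported arm summaries; no
  within-participant correlation adjustment is attempted.
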