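# Methods

## Design model

The trial randomizes `n` drivers to three arms (control, fear-appeal,
social-norming) through a four-step mechanism. A logistic propensity
model `P(baseline consistent | x) = expit(α + xᵀβ)` is fit by IRLS
maximum likelihood on baseline covariates (default set: district, age,
education, marital status, children, household size, driving setting,
night/speeding/weekend driving frequency; configurable). Drivers are
stratified by baseline consistency, sorted within stratum by propensity
score — ties broken by stable input order — and grouped into
consecutive triplets starting from the lowest scores; the 1–2
highest-score drivers left at the end of a stratum form a short
"leftover" unit. Each complete triplet draws, uniformly with
replacement, one of the six permutations assigning its score-ordered
members to arms (A=control, B=fear, C=social by default; relabeling is
configurable); a leftover unit draws a permutation and takes its first
position(s), i.e. it behaves as the low end of its own triplet. With
strata of 207 and 184 this yields 69 + 61 complete triplets, one
leftover, and arm sizes {130, 130, 131}.

Covariate item missingness is handled at randomization time by mode
(categorical) / median (numeric) imputation fitted on the full sample —
used only for scoring, never for outcome analysis. Quasi-separation of
the propensity fit is flagged, not fatal: the scores are only used for
ordering.

## Estimation

Odds ratios come from the 2×2 cross-product or, equivalently, from an
IRLS logistic fit of the observed-outcome subset on an arm indicator;
the two routes agree to ≥6 decimals and both are exposed. Adjusted
specifications add dummy-coded controls (default: marital status,
driving setting, night and weekend driving frequency) on complete
cases, with the dropped-row count logged. Ordered frequency scales are
dummy-coded rather than integer-scored: no scoring was given in the
source design, and dummies are assumption-free. Collinear design
columns raise an error naming the columns; constant columns within a
subgroup are dropped as uninformative. A constant outcome yields a
zero arm coefficient with a flat-likelihood flag rather than an
exception.

Reporting conventions: odds ratios rounded half-away-from-zero to 2
decimals, percentages and percentage-point differences to 1 decimal.
Difference-in-differences is computed from unrounded proportions; for
the packaged tables this agrees with rounded arithmetic.

## Randomization inference

P-values are obtained by rerandomizing under the actual assignment
mechanism: independently per unit (triplet or leftover), a uniform draw
over the six permutations relabels arms; the statistic is recomputed on
each relabeled dataset. Because assignments are permuted over the full
roster and the statistic is evaluated on whatever subset has observed
outcomes, wave-wise attrition travels with the individual and the
permuted assignment distribution equals the original randomization
distribution — the requirement for randomization-test validity.

Conventions and numerical choices:

- one-sided p = `#(T_perm ≥ T_obs)/B` with the log-OR oriented toward
  the hypothesized benefit of the exposed arm; two-sided
  p = `#(|T_perm| ≥ |T_obs|)/B`. Ties count as exceedance. The
  plain-fraction estimator is the default; the finite-sample-valid
  `(r+1)/(B+1)` variant is available (`plus_one=True`).
- default B = 10,000 for count-based statistics, 5,000 for
  covariate-adjusted ones (each adjusted draw refits a GLM).
- separation in a permuted 2×2 yields a sign-preserving ±∞ statistic,
  which the exceedance rules handle naturally; a draw undefined on both
  diagonals (0/0) is excluded, and the test aborts if more than 10% of
  draws are undefined. If the statistic is undefined under *every*
  relabeling (e.g. a constant outcome), the statistic is constant by
  symmetry and p = 1.
- effect modification uses the log ratio of stratum odds ratios as the
  plug-in statistic, two-sided.
- everything is seeded; identical seed and plan give bit-identical
  results. For ≤8 units an exhaustive-enumeration oracle over all `6^U`
  equally likely assignments is provided and used to validate the
  sampled engine.

Holm–Bonferroni step-down is applied to the primary family — the three
all-observations pairwise comparisons: sorted p-values are compared
with `α/(m−i+1)`, stopping at the first failure; adjusted p-values are
the running maximum of `(m−i+1)·p(i)` capped at 1.

## Balance diagnostics

Pearson chi-square without continuity correction for categorical
variables (this is what reproduces the published statistics), one-way
ANOVA for age and household size, each on its own complete cases so the
per-variable `n` varies with item missingness. Degenerate margins raise
errors naming the offending level or arm.

## Synthetic generator

`TrialConfig` defaults encode the study conditions: 391 drivers,
baseline consistent-wearing rate 207/391 ≈ 0.53, covariate marginals
pooled from the published balance table (age ~ N(28, 6.3²) truncated at
18, household size ~ N(5.13, 2.6²) truncated at 1), control-condition
week-6 transitions of 40/60 ≈ 0.667 (consistent stay consistent) and
18/50 = 0.36 (inconsistent become consistent), and MCAR attrition of
0.10 (week 3) and 0.12 (week 6) per wave relative to the roster, which
reproduces the 391 → ~352 → ~344 denominator pattern. Default item
missingness on covariates is 1.5%, the order of magnitude seen in the
published per-variable denominators.

Outcomes follow a two-wave transition model on the log-odds scale:
`P(consistent at wk6 | arm, stratum) = expit(logit(p0[stratum]) +
effect[arm][stratum])`. Default effects are calibrated to the published
stratum odds ratios (fear: ln 0.70 / ln 1.66; social: ln 1.61 /
ln 1.84). The week-3 effect is the week-6 effect scaled by a
configurable fraction, default 0.5 — the source trial saw group
differences at six weeks but not three, and no attenuation factor was
quantified, so the half-effect default is an explicit placeholder
exposed in the config.

What the generator does *not* emulate: covariate–outcome dependence is
off by default (so the propensity model estimates a flat score; a
`covariate_dependence` knob links night/speeding frequency to baseline
adherence when nontrivial matching is wanted), attrition is
missing-completely-at-random by default, and self-report
(social-desirability) misreporting is not modeled — no parameters for
it exist. Passing tests therefore demonstrate correctness of the
*pipeline under the design's assumptions*, not robustness to
informative missingness or measurement error in real field data.

### Estimands and non-collapsibility

A configured effect is a *stratum-conditional* log-odds shift. The
marginal (all-observations) odds ratio it implies is attenuated toward
the null because the odds ratio is non-collapsible over the stratum
mixture; `implied_marginal_proportions` gives the closed form. Effect
recovery is therefore checked on matching estimands: the
stratum-conditional estimator (logistic model with a baseline-stratum
indicator) against the configured conditional OR, and the marginal
estimator against the closed-form implied marginal OR. Conflating the
two would show a spurious ~4% "bias" at the study's mixture.

## Aggregate-table reconstruction

The participant-level data of the source trial were never deposited;
the packaged fixtures are its printed count tables. `fixture_roster`
expands them into a minimal roster (arm, baseline stratum, week-3/6
outcomes with the printed missingness) on which every unadjusted point
estimate is exact. Two caveats are inherent: the week-3 stratum split
is not printed (week-3 outcomes honor arm-level counts only), and the
realized triplet composition is unknown — triplets are reconstructed
by pairing one member per arm within stratum after a deterministic
shuffle (fixed `pairing_seed`), so permutation p-values on this roster
are labelled approximate. The shuffle matters: pairing in sorted-
outcome order would fabricate within-triplet outcome correlation and
badly understate p. The covariate-adjusted specifications cannot be
reproduced from aggregates at all; they are validated as regression
contracts on synthetic data instead.

## Problem sizes and tolerances

Simulation-based checks use: 400 null trials at n=391 with B=500 for
test size (the O(1/B) discreteness of the plain-fraction p is well
inside the 3-SE Monte Carlo band); 300 replicate trials for effect
recovery; B=20,000 against exhaustive enumeration on 5–6 triplets
(7,776–46,656 assignments); 60,000 draws for permutation-frequency
uniformity; 21,600 draws against the 216 joint arrangements of three
triplets. Monte Carlo assertions use 3-SE bands (2-SE for the recovery
bias check). IRLS uses statsmodels GLM/Binomial with tight tolerances;
|coefficient| > 15 on the logit scale is flagged as (quasi-)separation.

## Known limitations

- Cross-sectional analysis per wave, as designed; no longitudinal or
  GEE modeling of the repeated measures.
- The leftover-of-two rule (draw a permutation, take its first two
  positions) extends the stated leftover-of-one rule; a two-driver
  remainder did not occur at the study's sample sizes.
- The one-sided exceedance rule resolves an ambiguity in "larger
  magnitude" by orienting the signed statistic toward the hypothesized
  benefit; the alternative absolute-value reading is what the two-sided
  test implements.
- Whether the observed assignment should be counted among the null
  draws is a convention; both the plain-fraction and +1 variants are
  exposed.
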