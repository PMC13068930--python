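# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test suite demonstrates.

## The two-stage model

**Stage 1 — normative brain age.**  Candidate regressors (linear, ridge,
SVR, random forest) predict chronological age from parcellated grey-matter
volumes at several granularities, in a healthy reference sample only.  Each
candidate is tuned by grid search on inner folds of an 80% training split
(stratified by age decile, so both partitions span the age range — the
split's stratification is a design choice recorded here), evaluated on the
untouched 20% hold-out, and the candidate with minimal hold-out MAE is
selected (ties: higher r, then lexicographic name) and refitted on the full
healthy sample.  The repeated outer k-fold breakdown (fold-wise MAE, plus
Pearson r pooled over each repeat's out-of-fold predictions and averaged
across repeats — pooling per repeat is stabler than per-fold r at small
fold sizes) is reported for diagnostics; selection uses the hold-out only.

**Age-bias correction.**  OLS of predicted age on chronological age, fitted
on the healthy training split and frozen; adjusted age = (predicted −
intercept)/slope; BAG = adjusted − chronological.  Because BAG on the
fitting set equals the OLS residual divided by the slope, mean BAG = 0 and
corr(BAG, age) = 0 there are algebraic identities, asserted to 1e−8
relative and 1e−6 respectively.  A slope below 1e−6 in magnitude aborts
with a degenerate-model error (the prediction carries no age signal and the
division would be meaningless).

**Stage 2 — exposome prediction of BAG.**  On the population set (disjoint
from the healthy sample by construction; overlap is a pipeline-integrity
error), BAG is predicted from curated exposome variables with repeated
nested CV (defaults 5 outer folds × 5 repeats, 5 inner folds).  Per fold:
confound residualization (intercept + age, age², sex, height, volumetric
scaling; coefficients from training rows), then standardization (training
statistics), then inner-fold grid search, then prediction of the test fold.
Metrics per fold: MAE, MSE, RMSE (=√MSE by construction), R² (coefficient
of determination on test folds — it can be negative, which distinguishes it
from a squared correlation), Pearson r.  Fold-mean r is primary; pooled
per-repeat r is reported alongside since either aggregation is defensible.
Sex is a covariate by default and can be moved into the predictors
(`sex_as_predictor`).

**Permutation test.**  B target shuffles, each re-running a k-fold CV
(default 5 folds, matching the outer layout).  p = (1 + #{null at least as
good})/(B + 1), where "at least as good" means ≥ for r and R² and ≤ for the
error metrics; the attainable floor is 1/(B+1) ≈ 0.002 at B = 500.  The
default reduced-cost mode freezes the hyperparameters most often selected
in the unpermuted run (full re-tuning per permutation is available via
`retune`); under the null the frozen-parameter CV is identically
distributed across shuffles, so calibration is preserved, and the test
suite verifies the p-value distribution is uniform under an independent
target.  BH-FDR is applied across the five metrics; the step-up is
implemented directly (q for the i-th smallest p is min over j ≥ i of
p₍ⱼ₎·m/j, clipped at 1) and is cross-checked in tests against both a
brute-force oracle and statsmodels.

**Shapley explanation.**  Attributions are computed on held-out folds only,
with each fold's frozen preprocessing applied first, and aggregated by
concatenation; a variable's contribution is its mean |φ|.  Linear models
use the exact closed form φᵢⱼ = βⱼ(xᵢⱼ − x̄ⱼ) with respect to the background
mean.  Other models use a permutation-sampling estimator: for each sampled
feature ordering, features flip one at a time from background values to the
sample's values and the marginal change in the background-averaged
prediction is credited to the flipped feature.  Marginal contributions
telescope along each ordering, so the local-accuracy identity
base + Σφ = f(x) holds to floating-point precision for any sampling budget;
the budget (default 4 orderings in antithetic forward/reverse pairs,
25 background rows, ≤ 100 explained samples per fold) controls only the
Monte-Carlo noise in how credit is apportioned among features.  The
identity is re-verified for every explained sample at tolerance 1e−6.
Fold stability is the mean pairwise Spearman correlation of per-fold
mean-|φ| rankings.  The univariate contrast fits, per variable on its
complete cases, OLS of standardized BAG on the standardized variable plus
confounds (standardized beta) next to the marginal Pearson r — the pair
that identifies moderators.

## Exposome curation

Chain order: participant uniqueness (first record kept; conflicting
duplicates logged with both values — the kept-first rule is a documented
choice, since deduplication order is otherwise unspecified), uninformative
response codes nulled ("do not know"/"prefer not to answer" style codes,
e.g. −1/−3), aberrant values nulled (out of range or invalid category;
cells holding a declared uninformative code are left to the previous rule
so the two tallies stay disjoint), durations derived (duration = assessment
age − onset age; onset after assessment ⇒ missing, logged; the raw onset
column is kept because life period and chronicity are distinct information),
then the availability filter: variables observed in fewer than `n_min`
participants, or in a single sex, are dropped (bound inclusive).  The
reference-scale `n_min` of 2000 out of a 34 365-participant population is
scaled by the cohort-size ratio for desk-scale runs.  No step imputes;
multiple imputation is deliberately out of scope (block-structured
missingness gives the conditional models too little shared support).
Categorical variables are ordinal-coded integers and standardized like
everything else, so each variable keeps a single attribution value.
Redundancy heatmaps use pairwise-complete correlations because block
missingness can empty listwise deletion.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
any particular population:

- Ages uniform on 44–82; sex Bernoulli(½); height sex-shifted Gaussian;
  volumetric scaling N(1, 0.03).
- An individual aging deviation d = Σ variable contributions + N(0, 2²)
  years.  Effective brain age = age + d.
- Regional volumes: interceptᵣ − slopeᵣ·(effective age) + sex and height
  terms, all multiplied by the scaling factor, plus N(0, 5²) noise;
  slopes ~ N(0.5, 0.2²) clipped positive.  Coarser granularities are
  grouped means of fine regions.
- Exposome variables are independent draws (normal, lognormal, ordinal,
  binary); the analysis-relevant covariance lives in the configured effect
  structure, not in a variable-variable dependence model.
- Contributions per effect kind (strengths in years per SD): linear s·z(x);
  nonlinear s·z(z(x)²) (U-shaped, ~zero linear association); duration
  s·z(duration); moderator/interaction s·z(x)·z(partner), which has zero
  population covariance with either factor — the moderator is marginally
  null by construction.
- Duration-type variables are emitted as *onset ages* so curation must
  derive the duration.  The underlying durations are drawn independently of
  age (onset = age − duration): this keeps d age-orthogonal by design.  If
  durations were instead derived from age-independent onsets, d would
  inherit a large age component, and any near-degenerate (e.g. binary)
  feature would let a deep tree model read confound values off its
  residualization imprint and "predict" that component — a genuine
  confound-leak pathway in residualize-X-only designs that the simulator
  deliberately avoids planting.
- Health flags: exactly round(0.7·n) participants are flagged non-healthy
  (one or more specific condition flags, or poor/fair self-rated health),
  sampled preferentially from the top |d| ranks (rank⁴ tilt).  The healthy
  minority forms the normative sample, mirroring reference cohorts where
  only a small fraction pass strict criteria.
- Block missingness (same participants missing a whole variable block)
  produces main / replication / variables-restricted style complete-case
  subsets; small rates of aberrant cells (9999) and uninformative codes
  exercise the curation rules.
- A single integer seed expands through named SeedSequence substreams
  (demographics, regions, gm_noise, exposome, deviation_noise, flags,
  missingness, glitches), so every table is independently reproducible and
  identical seeds give byte-identical outputs.

**Default planted battery** (10 effects + 50 nulls): five linear effects of
both signs (|s| 1.0–2.0), one U-shaped nonlinear (1.5), two durations (2.5
each), one moderator (4.0, partner the strongest linear risk factor).  The
duration strengths compensate the credit split between the kept onset
column and the derived duration (post-residualization they are nearly
collinear); the moderator strength compensates the partial capture of pure
interactions by tree ensembles at desk-scale n — both are analytic
consequences of the design, chosen so that planted recovery is expected
when the pipeline is correct, and fixed once.

**What passing tests do not show.**  The generator draws variables
independently, has no real atlas topology, no genetic structure, no
longitudinal visits, and its signal-to-noise (exposome r ≈ 0.65 on the main
subset) is far above what heterogeneous population data yield; passing
recovery tests demonstrates the pipeline's correctness and leakage
discipline, not expected real-data effect sizes.

## Problem sizes and numerical choices

Desk-scale defaults: n = 3000 participants, 100 fine regions with levels
(100, 50, 25), brain-age candidates ridge at each level with 5-fold CV ×1
repeat and 5 inner folds, random forest (40 trees, √p features, depth grid
{6, 12}) for the exposome stage, B = 99 permutations in reduced-cost mode,
Shapley on ≤ 100 samples per fold with 25 background rows.  The full-scale
protocol (10-fold × 5 repeats × 10 inner; B = 500; full re-tuning) is
available through the same configuration objects.  Other numerics: ties in
model selection broken deterministically; zero-variance columns get unit
scale in standardization (residual stays zero); confound designs are
rank-checked before solving; rows are sorted by participant id inside the
CV so results are invariant to input row order; permutation p-values use
the add-one estimator, never 0.

## Known limitations

- The permutation test's reduced-cost mode understates the variability
  that re-tuning would add to the null; with the small grids used here the
  difference is negligible, and full re-tuning is one flag away.
- The sampling Shapley estimator's per-feature credit (not its sum) carries
  Monte-Carlo noise at the default budget; rankings of similar-strength
  variables can swap between runs with different explanation seeds.
- Complete-case subset construction, as in the reference design, can bias
  toward participants with more complete assessments; the generator's
  missingness is independent of d, so this bias is absent from the tests.
- BAG inherits any systematic error of the brain-age model; the pipeline
  reports hold-out brain-age performance next to the exposome metrics so
  this can be judged per run.
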