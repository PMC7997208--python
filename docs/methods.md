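# Methods

## Problem setting

The analysis targets early (first 48 h) identification of multi-drug
resistance in ICU episodes. Each episode n contributes a feature vector
x(n) of 12 mixed-type clinical and demographic variables and a binary label
y(n) (1 = an MDR germ was confirmed for that episode). Non-MDR episodes
outnumber MDR ones roughly 10:1 (2743 vs 270 in the emulated cohort), which
shapes both halves of the package: the feature-selection layer works on
class-stratified resamples, and the learning layer treats the imbalance
explicitly.

## Synthetic cohort generator

Real episode tables of this kind are not public, so the package includes a
class-conditional generator whose defaults reproduce the published
descriptive statistics of a 3013-episode cohort:

| variable | MDR class | non-MDR class | source of default |
|---|---|---|---|
| age (yr) | mean 63, SD 15, support [18, 100] | mean 60, SD 15 | means published; SD is a calibration knob |
| Apache II | 19.17 ± 6.91, support [0, 71] | 17.43 ± 7.66 | published |
| Charlson | 1.44 ± 1.65, support ≥ 0 | 1.24 ± 1.52 | published |
| SAPS III | 21 ± 8, support [0, 120] | 17.5 ± 8.5 | calibration knob (only banded rates published) |
| MV ratio | Beta, mean 0.44, concentration 5 | mean 0.39 | means published; concentration is a knob |
| surgical category | Bernoulli 0.4014 | 0.4481 | published |
| gender (male) | 0.615 | 0.615 | overall rate published; MDR prevalence is near-equal per gender, so the class-conditional rates are set equal |
| illness flag | 0.78 | 0.70 | qualitative (higher for MDR) |
| departments / reasons / disease groups | rank-decaying vectors with modal boosts | same construction | qualitative (modal categories and tilts published as figures only) |
| antibiotic families | 21 independent Bernoulli flags; PAP/CAR raised for MDR, CF3/PEN/QUI for non-MDR | | qualitative |

Numeric scores are drawn from support-truncated Gaussians. The parent
location is solved (Brent root-finding on the truncated mean) so that the
mean of the *truncated* distribution equals the configured value exactly;
with the published SD as the parent scale. For Apache II or age the
truncation is mild and the realized SD is essentially the configured one.
For the Charlson index the published moments (1.44 ± 1.65) have a
coefficient of variation above 1, which no Gaussian truncated at zero can
attain (the limit is 1); the generator therefore matches the mean exactly
and accepts a realized SD of ≈ 1.05. The MV ratio uses a Beta law
parameterized by (mean, concentration) so its configured mean is exact on
[0, 1]. Antibiotic families are independent Bernoulli flags because an
episode can receive several families at once.

Label counts are exact by construction (270 of 3013), not binomial. Each
(class, variable) pair draws from its own RNG substream keyed by a stable
hash of the variable name, so adding or reordering variables does not
perturb the draws of the others; a final seeded permutation interleaves the
classes.

What the generator does *not* emulate: correlation between variables within
a class (scores are mutually independent given the class), repeated
episodes of one patient, temporal drift over the 13-year collection window,
and missingness. Tests passing on this generator therefore validate the
statistical machinery and its calibration, not clinical transportability.

## Encoding

Categorical variables are expanded by *full* one-hot encoding — no
reference category is dropped, which is what makes the design width
27+32+7+21+3+5 = 95. Binary variables stay as single columns; exposure
flags pass through. Columns are named `variable=category` in schema order,
so selection reports are stable across runs.

## Bootstrap feature selection

*Averaged tests.* R resamples (default 3000) are drawn with replacement,
stratified by class so every resample keeps the 270/2743 split — unstratified
resampling would occasionally produce near-empty MDR samples at this
imbalance. Binary features use the pooled-variance two-proportion z test;
numeric features use Mood's median test (2×2 above/not-above grand median
table, Pearson χ² with 1 df; values equal to the grand median count as
"not above"). Per-resample χ² values are converted to p-values and the
*p-values* are averaged — comparing a mean χ² statistic directly with a
significance level is not meaningful. Features with mean p < α = 0.05 are
selected; no multiple-testing correction is applied across the 95 features
(α is per-feature by design). Degenerate resamples (pooled proportion 0 or
1, constant vector) contribute p = 1.

*Averaged mutual information.* Same resampling scheme; MI in bits from the
empirical joint table, numeric features discretized into 10 equal-frequency
bins within each resample (bin count configurable; the base of the
logarithm does not affect a top-k selection). Selection takes the top k by
mean MI; k defaults to the size of the test-based selection, which is the
natural way to compare the two rankings at matched cardinality. Ties at the
k-th value break lexicographically.

*Difference confidence intervals.* Per-class subsamples are drawn *without*
replacement, by default half of each class. Half-subsampling is deliberate:
the variance of a statistic of a without-replacement subsample of fraction f
is ((1−f)/f) times the sampling variance at full size, so f = 0.5 makes the
subsampling distribution's spread match the sampling variability of the
full-sample difference and gives the interval near-nominal coverage. Larger
fractions (e.g. 0.8) shrink the spread by half and inflate the null
false-selection rate to ~30%. The interval itself is the bootstrap
standard-error (normal-theory) interval, mean ± z·SD over the R
differences; raw percentile endpoints are noisy at a few hundred resamples
(endpoint SD ≈ 0.19 of the spread at R = 200) and measurably inflate the
null selection rate, while the normal interval is stable in R. The
percentile interval remains available (`ci_method="percentile"`); BCa and
studentized intervals are out of scope. A feature is selected when its
interval excludes zero; a constant feature yields the degenerate interval
[0, 0], which contains zero.

Known limitation: for very rare binary features (active rate ≲ 2%, i.e.
expected MDR-class counts below ~5) the difference-of-proportions statistic
is markedly skewed and *no* symmetric resampling interval is well
calibrated — the null false-selection rate rises toward 10–13% regardless
of R or interval type. The calibration tests therefore use well-populated
null features; on the full 95-column design, rare one-hot categories
contribute a mild excess of spurious CI selections, which the union
inherits.

*Union and correlation screen.* The final set is the union of the three
selections. All within-union pairs are scored with Pearson correlation
(numeric–numeric) or Spearman correlation (any pair involving a binary
feature); pairs at or above |r| = 0.9 drop the member with the worse
average rank across the three methods (rank by mean p ascending, mean MI
descending, and distance of the CI from zero descending). On cohorts like
the default one the strongest correlations (severity scores with each
other, modal department with surgical category) sit near 0.6, so the
default screen drops nothing.

Everything is deterministic given the configuration seed; the three
strategies use disjoint derived substreams so each can be re-run
independently.

## Imbalance benchmark

Stratified 80/20 train/test partitions, repeated 50 times by default (the
partitions are shared across model families and balancing strategies so
comparisons are paired). Within each partition, hyperparameters are tuned
by exhaustive grid search under stratified 5-fold CV with AUC as the
criterion; the balancing strategy is applied inside each fold's training
split only, then the model is refit on the full training split with that
strategy and scored on the untouched test split.

*Undersampling* keeps all minority samples and draws the majority down to
the minority count without replacement (so a training split with N₁′
minority samples trains on exactly 2·N₁′). *Weighted cost* keeps all N_t
training samples and multiplies each sample's loss term by its class
weight β₀ = N_t/(2N₀) or β₁ = N_t/(2N₁); the weights are carried as exact
rationals so the balance identity β₀N₀ = β₁N₁ = N_t/2 holds without
rounding, and they reduce to 1 when the classes are balanced.

Model families: logistic regression with ridge penalty (C grid
{0.01, 0.1, 1, 10, 100}), CART with Gini splits (depth/min-split/min-leaf
grids — the conventional *minimum* samples-per-leaf control stands in for a
terminal-node size limit), gradient-boosted trees (ensemble size, depth,
learning rate), and single-/multi-layer perceptrons with sigmoid output
trained by full-batch Adam on the weighted binary cross-entropy. LR, CART
and XGBoost delegate to scikit-learn/xgboost through their `sample_weight`
interfaces; the perceptrons are implemented in the package so that
per-sample weighting enters the gradient exactly. Numeric columns are
standardized with train-split moments for LR and the perceptrons; trees
see raw features. Class assignment for accuracy/sensitivity/specificity
uses a 0.5 threshold on the score; AUC uses the Mann–Whitney rank
formulation with ties counting one half. Sensitivity takes MDR as the
positive class.

Results are mean ± SD per (family × strategy) over the partitions. On the
calibrated synthetic cohort the qualitative pattern expected at this
imbalance holds: weighted-cost variants of the linear models match or beat
their undersampling counterparts in mean AUC, because the weighted models
train on ~2400 samples instead of ~430.

## Problem sizes in the tests

The acceptance suite scales the published protocol to desk-size runs as its
own study design: bootstrap checks use R = 200–1000 resamples (the paper
default of 3000 is kept for production configurations), null calibration
aggregates over 20 replicate effect-free cohorts of 55 well-populated
features, planted-effect recovery uses five replicate cohorts at full size
(N = 3013, 18 informative features among 95), generator calibration
averages over ten replicate cohorts (the n = 270 class mean of a single
cohort carries a sampling SE of ≈ 0.43 Apache II points, larger than the
calibration tolerance itself), and the benchmark property checks run 10–25
partitions with the linear families.

## Numerical and degenerate-input conventions

- p-value conventions: pooled proportion 0/1 → p = 1; degenerate median
  table → p = 1; single-class labels → MI = 0 with a warning, AUC = NaN
  with a warning.
- Equal-frequency binning merges duplicate quantile edges (heavily tied
  features yield fewer than 10 bins).
- Grid-search ties resolve to the first point in grid declaration order;
  MI top-k ties resolve lexicographically; the correlation screen processes
  pairs strongest-first.
- All RNG streams derive from `numpy` `SeedSequence`s keyed by (seed,
  stage), so stages are independently reproducible and byte-identical
  under a fixed configuration.
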