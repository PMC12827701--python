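# Methods

This note records the model conventions, the synthetic-data mechanism,
the numerical choices, and the known limitations of `caredemand`.  It
states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## The health signal

The method treats each individual's static tabular record as a 1D
sequence so that multiresolution signal analysis applies.  The
construction is deliberately simple and fully documented, because any
such synthesis is a modelling artifact rather than a measurement:

* variables are min-max normalized with statistics frozen on the
  training sample (test values clip to [0, 1]; a variable constant in
  training maps to 0.5);
* the ordered base vector (the seven core variables in their canonical
  order, then extra columns alphabetically) is tiled head-to-tail and
  truncated to length L = 64 = 2⁶.

Tile-and-truncate preserves each variable's exact normalized value;
the induced periodicity is an acknowledged artifact.  Interpolation
was rejected because it manufactures intermediate values with no
subject-matter meaning.  Min-max rather than z-score normalization
keeps the signal in the conventional [0, 1] range for wavelet feature
work.  L = 64 supports the default three-level decomposition with
band lengths 32/16/8/8.

## Wavelet feature extraction

The default family is the orthonormal Haar wavelet (db4 available via
configuration); decomposition depth J = 3; signal extension is
periodic (`periodization`).  With orthonormal filters and periodic
extension the transform is exactly energy-preserving, which gives two
machine-checkable invariants: band energies sum to ‖x‖² and the
inverse cascade reproduces the input, both to 1e-8.

Per band (cA_J, cD_1..cD_J) the package computes population
(1/N-normalized) mean, variance, standard deviation, skewness m₃/σ³
and kurtosis m₄/σ⁴ (zero-variance bands define both as 0), band
energy, and a complexity feature; globally it adds the wavelet energy
entropy and the full-signal sample entropy (30 features at J = 3).
"Complexity" is implemented as per-band sample entropy, matching the
method's use of sample entropy as its nonlinear measure.

Sample entropy uses embedding dimension a = 2 and tolerance
b = 0.2·sd (the literature standard), Chebyshev distance,
self-matches excluded, and N−a templates at both dimensions a and
a+1 so the a+1 match count can never exceed the a count.  When either
count is zero the value is undefined (+∞) and is reported as a
configurable cap, default ln(N−a) + ln 2 — the usual finite surrogate.
A constant series yields 0.  All entropies are in nats.

Two printed-formula ambiguities in the source method are resolved the
standard way: the variance summand carries its square, and the sample
entropy ratio is count(a+1)/count(a), the orientation that makes the
statistic non-negative.

## Feature scoring and adaptive threshold

Continuous features are discretized into equal-frequency bins
(default 10) on unique quantiles; integer-valued features with at
most 10 distinct values pass through as categories.  Equal-frequency
binning is robust to the heavy-tailed expenditure variable.  The gain
ratio is Quinlan's information gain over feature entropy; a constant
feature scores 0.  Both conditions of the adaptive threshold are
strict inequalities joined by AND; α = β = 0.5 by default (the
best-performing coefficient in the threshold study that motivated the
rule).  An empty strict mask falls back to the single feature with
maximal IGR + MI, so selection never returns nothing.

One consequence worth knowing: because the gain ratio divides by
H(F), a low-cardinality feature (few distinct values, small entropy)
gets a systematically inflated IGR relative to finer-grained features
of equal predictive strength.  The candidate pool defaults to the
union of raw normalized variables and derived wavelet features; `raw`
and `derived` pools are configurable.

## Weighted forest

Defaults: 500 trees, maximum depth 10, minimum leaf size 5, mtry =
⌊√p⌋.  Trees are CART (Gini) fit on n-of-n bootstraps by
scikit-learn's splitter and immediately flattened to an in-package
array form used for all prediction and JSON serialization (saved
models carry no estimator objects).  Split tie-breaking therefore
follows the library's seeded convention; reproducibility under a
fixed seed is the contract and is tested.  Per-tree accuracy A_t is
measured on that tree's out-of-bag rows — the only leakage-free
per-tree accuracy available inside bagging; the rare empty-OOB tree
receives the neutral A_t = 0.5.  Votes are hard class indicators
weighted by w_t = A_t/ΣA_t.  The aggregate OOB error scores each
training sample using only trees for which it is out of bag.
Permutation importance shuffles one feature within each tree's OOB
rows (5 repeats by default) and averages the error increase over
trees; a feature used in no split has importance exactly 0.

## Logistic regression by batch gradient descent

Full-batch gradient descent on mean cross-entropy, learning rate
0.01, 500 iterations, zero initialization; features are z-scored
internally (the fixed step size is only sensible on standardized
scales) and coefficients are mapped back to the input scale.  No
regularization.  With standardized features this step size descends
monotonically — the convex objective's curvature is bounded by ~1/4 —
and that is asserted in tests.

Known quantitative limitation, by construction: plain gradient
descent contracts the coefficient error by roughly (1 − 0.01·λ) per
step with λ = mean h(1−h) ≈ 0.2, so 500 iterations from zero retain
about e⁻¹ of the distance to the maximum-likelihood solution.  For
unit-scale true coefficients the fitted values are therefore ~0.3
short of a Newton/IRLS fit; the tests assert this contraction
behaviour and show a longer run (5000 iterations) closes the gap.
The configured hyperparameter set also lists a batch size of 32 that
contradicts the full-batch choice; full batch is the default and a
mini-batch mode is available behind `batch_size=` (mini-batch updates
converge much faster per epoch but forfeit monotone descent).

## Fusion and evaluation

P_final = g·P_RF + (1−g)·P_LR with g = 0.5 by default; `tune_g` grid
searches g ∈ {0, 0.05, …, 1} by validation AUC, breaking ties toward
0.5 (the least-committal blend).  Classification threshold 0.5,
configurable.  ROC is swept over all unique score thresholds; AUC is
trapezoidal, equal to the rank statistic with half-credit ties (the
in-package rank implementation is cross-checked against the library
curve in tests).  Cross-validation is stratified k-fold with the
*entire* pipeline — normalizer, feature extraction, scoring,
selection, both learners — refit inside every training fold, so no
test-fold statistic leaks into training; shuffled-label runs sitting
at AUC 0.5 confirm this.  Confidence intervals are percentile
bootstrap (B = 1000, level 95%); resamples with a single class are
redrawn (at most 100 retries).

## The synthetic cohort

Marginals are documented fixtures with plausible shapes for the named
variables — counts Poisson (chronic 2.5, hospitalizations 0.8,
medications 4), bounded scores scaled binomial (ADL B(24,.7), IADL
B(16,.75), mental B(30,.6)), expenditure log-normal(8,1) — and the
label follows a known logistic mechanism: standardized variables
enter η with chosen log-odds, plus a chronic×ADL product term; the
intercept is calibrated by bisection (tolerance 1e-4 on the mean
probability) to hit the target prevalence; noise columns are standard
normal and label-independent.

The standard study cohort plants chronic +1.75, ADL −2.0, medication
+1.75 (log-odds per SD), interaction +1.25, prevalence 0.35, five
noise features, n = 2000.  These magnitudes were chosen once, for two
reasons.  First, the label's intrinsic Bernoulli noise caps the
achievable AUC: ±1 SD effects cap it near 0.87, too low to separate
estimator quality from noise, while this configuration has a Bayes
AUC near 0.92 — comparable to a strong published risk model.  Second,
detectability must be commensurate across the planted set: the
symmetric binomial ADL score carries less binned mutual information
per SD of effect than the skewed Poisson counts, so functional
dependency — in any case the dominant driver of care need — carries
the largest magnitude.

What the generator does *not* emulate: survey weights, panel
structure, informative missingness (only optional MCAR), measurement
error, and real between-variable correlation (variables are
independent given the mechanism).  Passing tests therefore certify
the algorithmic machinery — recovery of planted structure under known
conditions — not performance on any real survey population.

## Problem sizes and runtime choices

Test and benchmark sizes are chosen to make the suite informative at
interactive runtimes: end-to-end benchmark 20 seeds × (train 2000 /
test 2000, 500 trees); OOB-vs-holdout 10 seeds at the same size;
bootstrap coverage 300 replicates of 200 observations at B = 1000;
shuffled-label cross-validation 10 seeds at n = 400 with a 50-tree
forest (the canary needs many refits, not a large ensemble).
`scripts/acceptance.py` averages three independent
train/test/validation replicates and one 10-fold CV at n = 600.

## Known limitations

* The health-signal construction is an artifact; derived wavelet
  features of tiled static variables are nonlinear recombinations of
  those variables, not temporal information.
* Gain-ratio comparability across features of very different
  cardinality is limited (see above).
* BGD at the default budget is deliberately not run to convergence.
* Binary targets only; no survey-design adjustments; no significance
  testing beyond bootstrap intervals.
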