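# Methods

## The measurement and pooling model

Gene expression is modelled gene-wise on the log2 scale. For gene *g* and
subject *i*, the biological value is X_g,i ~ N(mu_g, sigma^2) i.i.d. across
subjects, and an array measurement adds technical noise:
Y_g,i = X_g,i + eps_i with eps_i ~ N(0, sigma_eps^2). Noise draws are
independent across genes and arrays (no array-wide effects), and noise is
applied uniformly to every column — background, differentially expressed,
and both genes of a linear pattern. The measurement model makes no
per-column exceptions because none would be identifiable from data anyway.

An ideal pool mixes equal RNA amounts from m_p same-class subjects, so its
biological expression is the arithmetic mean on the *raw* scale. Simulated
log2 values are therefore exponentiated (base 2), averaged within the pool,
and re-logged. Two consequences are asserted by the test suite:

* Jensen's inequality — the pooled log2 value is at least the mean of the
  member log2 values (2^x is convex), strictly unless the pool is constant.
* For small sigma the pooled biological values have variance close to
  sigma^2/m_p (the raw/log discrepancy is second order at sigma = 0.2; the
  tests require agreement within 5%).

Each pool is hybridised on one array, so exactly one technical-noise draw
is added per pool and gene *after* averaging. Pools are formed from
biological values, never from measured ones — pooling happens at the RNA
level, before measurement. There is no pooling-error term beyond the
averaging itself; imperfect mixing is out of scope.

`design_variance` gives the variance of a class mean in the two designs at
equal subject count n = m_p * n_P: (sigma^2 + sigma_eps^2)/n for single
samples and (sigma^2/m_p + sigma_eps^2)/n_P for pools. With technical noise
the pooled design is *worse* (fewer arrays average fewer noise draws); the
designs coincide when sigma_eps = 0. Note the formula treats averaging on
the normal scale, whereas the data pipeline pools on the raw scale; the two
agree only approximately, and the package makes no attempt to reconcile
them beyond the 5% check above.

## Scenarios and their parameters

All defaults are the benchmark's reference conditions:

| parameter | default | meaning |
|---|---|---|
| n_per_class | 30 | subjects per class (60 x 1000 matrix) |
| n_features | 1000 | feature columns |
| background_mean, bio_sd | 8, 0.2 | background N(8, 0.2^2), log2 scale |
| n_de_genes | 10 | scenario-1 block size |
| de_delta_interval | [0.1, 0.5] | per-gene class shift Delta ~ U |
| class_mean_interval | [6, 10] | per-gene class-A mean mu_A ~ U |
| n_patterns | 10 | scenario-2 block: 10 pairs (g1, g2) |
| pattern_offset delta | 0.4 | class-B offset on g2 |
| noise_sd | 0.2 or 0.4 | technical noise sd per array |
| pool sizes | 1, 2, 3, 5 | m_p = 1 is the single-sample design |

The linear pattern is exact on biological values: g2 = 2*g1 (class A) and
g2 = 2*g1 + delta (class B), with one shared mean mu ~ U[6,10] per pattern
for g1 in both classes. The construction also induces a marginal mean
difference of exactly delta on g2, which the acceptance suite verifies both
algebraically and by simulation. Informative columns occupy the leading
positions by default; a `shuffle_columns` flag randomises their positions
for robustness checks (classifiers are column-order agnostic, so results
are unchanged in distribution).

## Repetition protocol

One repetition realises the gene-level parameters (mu_A, Delta per DE gene;
pattern means) once, then draws a training and a test dataset from the same
conditional distribution. Sharing the realised parameters within a
repetition is essential: the class boundary of scenario 1 sits at
mu_A + Delta/2 with mu_A ~ U[6,10], so a test set with independently
redrawn means would be unlearnable from the training set (error ~0.5 for
every method). Across repetitions everything is redrawn, including pool
membership (sampled without replacement within class).

Training sets are pooled at m_p and measured (one noise draw per pooled
array); test sets are always 60 fresh *single* samples, classified on
their biological values. Evaluating on noise-free test samples is a
deliberate protocol choice: pooling and technical noise are properties of
the training design under study, and the benchmark's reported error levels
(e.g. t-test+LDA at ~0.03/0.09/0.19 for m_p = 1/2/3 in scenario 1, low
noise) are only attainable this way — with noisy test samples even the
Bayes rule on the true DE genes averages ~0.05. The `test_noise` config
flag restores noisy test evaluation for sensitivity analyses.

Within a repetition all methods and pool sizes see the same training and
test data (paired comparison; an unpaired mode exists behind a config
switch). Seeds derive from numpy `SeedSequence` tuples
(base_seed, scenario, noise, repetition[, pool, method]), so any cell can
be reproduced in isolation and runs are bit-reproducible end to end.

The prediction error of a repetition is the fraction of misclassified test
samples (granularity 1/60). Cell summaries report the mean over
repetitions with a percentile-bootstrap confidence interval for the mean
(1000 resamples, level 0.95 by default; the bootstrap flavour and resample
count are conventional choices).

## Classifiers

All five methods sit behind one fit/predict contract and are trained on
the measured (pooled) matrix only.

* **SVML** — soft-margin linear SVM, cost C = 1 (the conventional default;
  the benchmark specifies no cost).
* **SVMR** — RBF-kernel SVM, C = 1; gamma selected by stratified inner
  10-fold CV over the grid 2^-10..2^2 times 1/n_features (a logarithmic
  grid around the common 1/p heuristic), ties to the smallest gamma.
* **RF** — 1000 trees, 20 candidate features per split, majority vote.
* **PPLS-DA** — powered partial least squares discriminant analysis,
  authored here. Per component, feature weights are
  w_g(gamma) = sign(rho_g) * (s_g/max s)^((1-gamma)/gamma)
  * (|rho_g|/max|rho|)^(gamma/(1-gamma)),
  where rho_g is the correlation of feature g with the class-coded
  response and s_g its standard deviation. gamma = 0.5 reduces to
  classical PLS (covariance weights, verified against an independent PLS
  implementation); towards 0/1 the weights truncate to the max-sd /
  max-correlation feature, so components can be driven by few features.
  gamma is optimised per component over a fixed 21-point grid in [0, 1]
  (the optimiser is not prescribed; a grid is deterministic and adequate at
  this resolution) by maximising corr(score, response)^2, ties to the
  smaller gamma. After each component the predictor matrix is deflated.
  The number of components (cap 10) is chosen by stratified inner 10-fold
  CV minimising misclassification count, ties to fewer components; folds
  are reduced to the smallest class size when a pooled training set is
  small. Classification uses a two-class Fisher discriminant on the
  component scores: direction Sw^+ (m1 - m0) with pooled within-class
  covariance Sw (pseudo-inverse for degenerate scatter) and a midpoint
  threshold.
* **t-test + LDA** — per-feature two-sample pooled-variance t-test (a
  Welch switch exists), the ten smallest p-values (ties by column index)
  select the features for a standard LDA. With pools of five there are
  only 12 training arrays for 10 features; the SVD-based LDA solver then
  effectively regularises the near-singular pooled covariance and the
  package emits a warning rather than failing.

## Problem sizes used by the checks

The reference benchmark uses 500 repetitions per cell. The package's own
verification runs use 500 repetitions for the t-test+LDA quantities, 200
per cell for PPLS-DA and SVM bounds (the means are stable to ~0.01 at that
count), 100 repetitions for feature-recovery rates, and 40–60 paired
repetitions for qualitative properties (chance-level error under null
effects; one-sided signed-rank tests of error degradation from m_p = 1 to
m_p = 5, which are overwhelmingly significant at these effect sizes). The
property checks scale the forest to 150–200 trees; tree count affects
variance, not the direction of any tested effect.

## What the generator does and does not emulate

The simulation captures the statistical skeleton of a two-class microarray
study: log-scale normality, per-gene means and effects, array-level
additive noise, raw-scale pooling, and the n = m_p * n_P sample-size
trade-off. It does *not* model normalisation artefacts, probe effects, dye
bias, missing values, correlated noise across genes, unequal pool
contributions (pool bias), or unbalanced classes. Passing tests therefore
demonstrate how pooling degrades classification under these idealised
conditions, not performance on any real platform; effect directions (error
growing with pool size, LDA's fragility, PPLS-DA's robustness) are the
transferable findings.

## Known limitations

* Two classes only; equal class sizes; pool size must divide the class
  size.
* The power-parameter search is a fixed grid, not a continuous optimiser;
  with 21 points the resolution of gamma is 0.05.
* The degradation ratio of t-test+LDA between m_p = 5 and m_p = 1
  (scenario 1, low noise) measures ~10 here; published figures place it
  above 12, with the discrepancy traceable to the single-sample error
  level (~0.04 vs ~0.03) rather than to the pooled one.
* Bootstrap intervals are percentile intervals for the mean; no BCa
  correction.
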