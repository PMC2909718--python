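# poolsim

A simulation framework for quantifying how **RNA sample pooling** degrades
**two-group classification of gene-expression biosignatures**.

Pooling RNA from several subjects onto one microarray is sometimes
unavoidable (limited RNA per sample), but it averages away inter-individual
variation and reduces the number of arrays available for training a
classifier. `poolsim` generates controlled two-class expression data,
applies an ideal raw-scale pooling operator to the training set, trains
five statistical learning methods, and measures their prediction error on
independent single-sample test sets — so that the cost of pooling can be
attributed to pool size, noise level, discriminating-pattern type and the
choice of method.

It is aimed at statisticians and bioinformaticians planning classification
(biomarker-signature) studies on pooled designs, or evaluating how robust a
classification method is to pooling.

## Model

Expression of gene *g* in subject *i* is simulated on the log2 scale as
*X*<sub>g,i</sub> ~ N(μ<sub>g</sub>, σ²); a hybridised array measures
*Y*<sub>g,i</sub> = *X*<sub>g,i</sub> + ε<sub>i</sub> with technical noise
ε ~ N(0, σ<sub>ε</sub>²). A matrix has 60 subjects (30 per class) × 1000
features with background N(8, 0.2²), and an informative block:

* **Scenario 1** — ten independent differentially expressed genes:
  class A mean μ<sub>A</sub> ~ U[6, 10], class B shifted by
  Δ ~ U[0.1, 0.5] per gene (1.07–1.4-fold changes).
* **Scenario 2** — ten bivariate linear patterns: *g*₂ = 2·*g*₁ for class A
  and *g*₂ = 2·*g*₁ + δ (δ = 0.4) for class B.
* **Scenario 3** — both.

An ideal pool of *m*<sub>p</sub> subjects averages on the raw scale:
pooled value = log2( mean(2^x) ), one technical-noise draw per pooled
array. The subject count is held fixed (*n* = *m*<sub>p</sub>·*n*<sub>P</sub>),
so larger pools mean fewer training arrays. Test sets are always fresh
single samples. Five classifiers are compared: linear- and radial-kernel
SVMs, random forests, a from-scratch **powered partial least squares
discriminant analysis (PPLS-DA)** with inner 10-fold CV for the number of
components, and a pooled-variance t-test selecting the ten best genes for
LDA. Per grid cell (scenario × noise × method × pool size) the mean test
error over repetitions is reported with percentile-bootstrap confidence
intervals.

## Worked example

```python
import poolsim as ps

cfg = ps.RunConfig(
    scenarios=("de_only",), noise_sds=(0.2,),
    pool_sizes=(1, 5), methods=("ttest_lda", "pplsda"),
    n_reps=100, base_seed=7,
)
res = ps.run_experiment(cfg)
print(res.summary[["method", "m_p", "mean_error", "ci_lower", "ci_upper"]])
```

prints (scenario 1, low noise, 100 repetitions):

```
      method  m_p  mean_error  ci_lower  ci_upper
0     pplsda    1    0.160167  0.145162  0.177508
1     pplsda    5    0.253667  0.236162  0.272500
2  ttest_lda    1    0.038000  0.030333  0.046504
3  ttest_lda    5    0.419500  0.390833  0.446171
```

Reading: with single samples (m_p = 1) the t-test+LDA pipeline misclassifies
~3.8% of independent test samples; training on pools of five degrades it
about elevenfold (~42%), while PPLS-DA degrades far more gracefully
(16% → 25%). The same experiment is available from the shell:

```bash
poolsim run --out results/ --scenario de_only --noise 0.2 \
    --methods ttest_lda,pplsda --pool-sizes 1,5 --reps 100 --seed 7
poolsim simulate --scenario combined --seed 1 --out data/   # one dataset as TSV
poolsim pool --data data/dataset.biological.tsv --labels data/dataset.labels.tsv \
    --pool-size 5 --out data/pooled/
poolsim summarize --records results/records.csv --out results/summary.csv
```

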