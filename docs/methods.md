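# Methods

This note records the statistical definitions, estimator choices, default
parameters and known limitations behind `omicschar`.

## Preprocessing

All characteristics are computed on a common representation: zeros and
infinite values are recoded as missing, remaining values are
log2-transformed. Zeros are treated as missing because different
technologies encode non-detection differently (NAs in proteomics, zeros in
sequencing counts); recoding makes matrices comparable, at the cost of not
distinguishing structural zeros from censored values. Matrices containing
negative values are rejected rather than silently accepted: negatives
almost always indicate an upstream log transformation, after which a
second log would be wrong.

Inclusion filters: ≥ 5 samples, ≥ 10 analytes, and strictly positive
total variance, median per-sample variance and median per-analyte variance
(each over observed entries; per-axis variances require ≥ 2 observations).
Duplicate datasets are detected by a content fingerprint taken after
sorting rows and columns by label, so relabeled re-uploads and
permutations of the same matrix collapse to one representative
(first-seen wins).

## Characteristic definitions and estimator choices

- **Variance** uses the n−1 denominator throughout.
- **Skewness / kurtosis** are the plain moment estimators g₁ and excess
  g₂ over the pooled observed values. No small-sample correction is
  applied; the landscape displays these as ranks, which are insensitive to
  the convention.
- **% distinct values** counts distinct observed values but divides by the
  total cell count including missing positions, mirroring
  `unique(mtx)/length(mtx)`; sparse count matrices therefore score low on
  both sparsity and distinctness axes.
- **Mean-vs-missingness correlations** are Spearman correlations between
  per-unit % missing and per-unit observed mean, undefined when either
  variable is constant (complete matrices) or fewer than 3 units qualify.
  Ties receive average ranks.
- **Detection-threshold spread.** Per sample, the missingness indicator of
  every analyte is regressed on the analyte's reference intensity (mean of
  its observed values across all samples, including the sample under
  test — excluding it changes estimates negligibly) with a two-parameter
  logistic model fitted by Newton/IRLS with step halving. Under hard
  censoring the classes are perfectly separated and the unpenalized MLE
  diverges; the iteration is stopped when either the deviance or the
  threshold crossing −β₀/β₁ stalls, at which point the crossing sits in
  the separation gap, which is exactly the quantity wanted. An estimate is
  usable only if the fit converged, the slope is negative, and the sample
  has both observed and missing analytes; the characteristic is the SD of
  the per-sample x₅₀ (or x₉₀) over usable samples, undefined with < 2.
  For datasets with > 200 samples a seeded uniform subset of 200 samples
  is used.
- **PCA variance fractions** come from a 2-component NIPALS fit of the
  transposed matrix (samples as observations), mean-centered per analyte,
  no scaling (raw intensities share a scale). Analytes observed in fewer
  than two samples are dropped as carrying no variance information.
- **Agglomerative coefficient.** Pairwise Euclidean distances between
  analyte profiles over pairwise-complete coordinates, rescaled by
  √(total/shared coordinates), average-linkage clustering, and the `agnes`
  banner coefficient: mean over analytes of 1 − h_first/h_final. Undefined
  when all analytes coincide (h_final = 0) or some pair shares no observed
  coordinate — common in heavily censored matrices, and reported honestly
  as undefined rather than imputed. For large matrices the 500 analytes
  with the fewest missing values (ties by row order) and a seeded subset
  of ≤ 500 samples are used. The linkage is configurable; average linkage
  is the default.
- **Mean–variance polynomial.** OLS of per-analyte variance on per-analyte
  mean and squared mean with intercept, requiring ≥ 3 analytes with ≥ 2
  observations and ≥ 3 distinct means.

A single integer seed drives all subsampling; `compute_all` is
deterministic given (matrix, seed) and records the seed in its output.

## NIPALS with missing values

Components are extracted sequentially by alternating least-squares updates
of score and loading vectors computed over observed cells only (no
imputation), initialized from the variable with the largest observed
variance, deflating after each component. Loadings are unit-norm with the
largest-magnitude entry positive (sign reproducibility). The per-component
variance fraction is the fitted sum of squares over observed cells divided
by the total centered observed sum of squares.

Convergence uses two criteria, whichever fires first: relative change of
the score vector < 1e-9, or relative stall of the fitted observed sum of
squares < 1e-10 (cap 5000 iterations, non-convergence flagged). The second
criterion exists because structured missingness can let the score norm
drift unboundedly (observations constrained only through sparsely loaded
variables) while the fitted sum of squares — the reported quantity —
converges; it also tracks the eigenvalue, which converges at twice the
exponential rate of the score direction. On complete 20×6 matrices the
variance fractions agree with SVD PCA to ~1e-7 (worst case over 200
seeds).

## Landscape

Reference tables drop data-type groups with ≤ 5 datasets (strict). Display
transforms: #samples, #analytes and variance are carried on the log2
scale; the two variance medians are log2-transformed for display only;
kurtosis, skewness and the two polynomial coefficients are shown as
average-tie ranks.

Characteristics are z-standardized (reference mean/SD of defined values)
before embedding: they live on incommensurable scales, so unscaled
embeddings would be dominated by whichever characteristic has the largest
numeric range. PCA embeddings use NIPALS (2 components) and tolerate
undefined values; UMAP cannot, so it first drops the four
missingness-dependent characteristics (undefined for every complete
dataset) — `Corr(Mean vs. % NA)` for samples and analytes and the two
detection-threshold spreads — and then any record still containing an
undefined value. UMAP runs with n_neighbors = min(15, n−1), min_dist 0.1,
Euclidean metric, fixed seed; these hyperparameters are recorded in the
model.

Projection of a new dataset standardizes with the *reference* center and
scale, then either applies the sequential NIPALS score regression
(skipping undefined entries, exactly reproducing reference scores) or the
stored UMAP transform. Percentiles use the tie-stable "mean of < and ≤"
definition against a chosen reference group.

## Missing-value mechanism simulator

Generative model on the log2 scale: analyte levels μ_i ~ N(grand_mean,
analyte_sd²), residuals ε_ij ~ N(0, residual_sd²), sample biases
b_j ~ N(0, sample_bias_sd²); truth g_ij = μ_i + ε_ij, measured
x_ij = g_ij + b_j. Censoring is a hard threshold (x_ij < t_j ⇒ missing)
with t_j ~ N(limit_center, limit_sd²) in sample mode, t_j ≡ limit_center
in batch mode, or value-independent Bernoulli dropout in random mode.
Missing entries are encoded as NA or as the value 0; the encoding flips
the sign of the mean-vs-%missing diagnostic because zeros enter sample
means while NAs do not.

Defaults: 200 analytes × 20 samples, grand_mean 20, analyte_sd 2,
residual_sd 1, limit_sd 1, limit_center resolved at run time to the 25th
percentile of the simulated intensities (substantial but non-degenerate
censoring). The default sample-bias spread depends on the mode:
sample-dependent censoring is simulated without true sample bias (the
censoring itself is the effect under study, and with bias spread equal to
threshold spread the two mechanisms' signals cancel), while batch mode
carries sample biases of SD 1 — with a shared threshold and no
between-sample shifts there would be no systematic mean/%NA signal at all.
These conditions are fixed; under them the sign dichotomy (positive for
sample-dependent NA-encoded censoring, negative for batch-dependent or
zero-encoded) holds in 100/100 seeded replicates.

**Quantile normalization** is NA-aware: every sample's sorted observed
values are interpolated to a common grid (length = number of analytes),
the reference is the per-rank mean of these curves, and each sample's
observed values are replaced by the reference interpolated at their rank
fractions (average ranks for ties; missing entries stay missing). On
complete data this is classical quantile normalization and an exact fixed
point when columns already share a distribution.

**Sample bias metric.** For each sample, the difference between the 90th
percentile of its observed values and the 90th percentile of its bias-free
truth restricted to the same observed entries; the metric is the SD of
these differences across samples. The 90th percentile is used because
low-intensity censoring barely touches it, and restricting the truth to
observed entries makes the comparison measure only genuine value
distortion: an NA-censored matrix without true bias scores exactly zero
before normalization, so any increase afterwards is attributable to the
normalization itself. (Comparing against full truth columns instead would
charge the censoring, not the normalization, and reverses the verdict in
the sample-dependent case.)

## Synthetic archetypes

The fixtures module generates five archetypes capturing the hallmark
characteristic patterns of major data types: complete Gaussian
log-intensities (microarray-like), sparse gamma-Poisson counts over many
cells (scRNA-seq-like: > 50% missing after zero conversion, < 5% distinct
values), threshold-censored Gaussian intensities (LFQ-proteomics-like:
positive sample mean-vs-%NA correlation), small lognormal matrices with
light random dropout (metabolomics-like), and heavy-tailed sparse counts
(microbiome-16S-like). Parameters are engineering choices that guarantee
these qualitative hallmarks for every seed; they do not claim to match
the population distributions of real repository data, so passing
landscape tests demonstrates that the pipeline separates the *mechanistic*
fingerprints, not that it reproduces repository-scale geometry. Reference
collections shrink the archetype dimensions by a factor 0.4 with ±20%
per-dataset jitter — large enough for every archetype's hallmark to
survive, small enough that a 40-dataset collection characterises in
seconds.

## Limitations

- The logistic probNA estimator is one reasonable choice; binned empirical
  estimators would give similar spreads but different per-sample values.
- The agglomerative coefficient's distance/linkage are not canonical;
  results depend on the linkage chosen (average by default).
- Zero-encoded data are normalized with the same quantile scheme as
  NA-encoded data; methods tailored to zero-inflated data are out of
  scope.
- No biological metadata (groupings, conditions) enters any
  characteristic.
- Readers assume well-formed input dialects (UTF-8, decimal point, unique
  labels); duplicate analyte identifiers are an error rather than being
  merged.
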