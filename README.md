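# omicschar

Data-characteristic extraction, landscape embedding, and missing-value
mechanism simulation for quantitative omics matrices.

## The problem

Benchmark studies and method choices in proteomics, metabolomics,
transcriptomics and microbiome analysis hinge on *data characteristics*:
how sparse a matrix is, how its intensities are distributed, whether
missingness is coupled to intensity through detection limits. Datasets
from different technologies differ systematically in these respects, so an
algorithm validated on one data type may behave very differently on
another — and a preprocessing step as routine as quantile normalization
can either remove or *create* bias depending on the missing-value
mechanism.

`omicschar` is for researchers who want to

- summarise any analyte × sample intensity matrix by a fixed panel of
  **29 data characteristics**,
- place a dataset in a characteristics-based **omics landscape** to judge
  how representative it is of its discipline, and
- **simulate** sample- vs batch-dependent detection limits to decide
  whether quantile normalization will help or hurt a dataset like theirs.

## The characteristic panel

All statistics are computed on log2-transformed intensities with zeros and
infinities recoded as missing (`mtx`, analytes *i* in rows, samples *j* in
columns). The panel covers:

- **size / distribution** — log2 #samples, log2 #analytes, mean, median,
  min, max, log2 variance, median per-analyte and per-sample variance,
  skewness g₁, excess kurtosis g₂, |skewness|, % distinct values;
- **missingness** — % NA overall, min/max per-analyte and per-sample % NA,
  % analytes and % samples containing NAs, and the Spearman correlations
  ρ(%NA, mean) across analytes and across samples;
- **detection thresholds** — per sample, a logistic fit of the missingness
  indicator against each analyte's reference intensity gives the intensity
  x_p at which P(missing) = p; the panel reports sd(x₅₀) and sd(x₉₀)
  across samples (large values ⇒ sample-dependent detection limits);
- **structure** — % variance explained by PC1/PC2 of a NIPALS PCA
  (missing-value tolerant) of the transposed matrix, the agglomerative
  coefficient of average-linkage clustering of analytes, and the linear and
  quadratic coefficients of the OLS fit var_i ~ mean_i + mean_i²
  (overdispersion shape).

Supported input formats: generic TSV, MaxQuant `proteinGroups` (iBAQ /
Intensity / LFQ column families), Expression Atlas FPKM/TPM tables (the
median — third of five comma-separated numbers — per cell), MatrixMarket
sparse counts with row/column sidecars, and microbiome taxon-abundance
TSVs. A registry enumerates the 16 supported data types and their 38
subgroups.

## Worked example

```bash
python examples/simulate_missingness.py
```

```
sample-dependent detection limits (sample_bias_sd=0.0, limit_sd=1.0):
  Corr(mean vs %NA) across samples: +0.981
  sample bias before normalization: 0.000
  sample bias after  normalization: 0.249
  quantile normalization is NOT recommended

batch-dependent detection limits (sample_bias_sd=1.0, limit_sd=1.0):
  Corr(mean vs %NA) across samples: -0.893
  sample bias before normalization: 0.972
  sample bias after  normalization: 0.276
  quantile normalization is recommended
```

Sample-dependent limits (each sample censored at its own intensity
threshold) leave the surviving values correct but produce a *positive*
mean-vs-%NA correlation; forcing all samples onto a common distribution
then distorts the censored samples, and the spread of the 90th-percentile
bias rises from 0 to 0.25 log2 units. Batch-dependent limits plus genuine
per-sample shifts produce a *negative* correlation; normalization removes
the shifts and the bias falls from 0.97 to 0.28. The sign of
`Corr(Mean vs. % NA) (Samples)` is therefore a practical pre-normalization
diagnostic.

Other examples: `examples/characterize_dataset.py` (the 29-value panel on
a proteomics-like matrix) and `examples/landscape_embedding.py` (PCA
landscape of five synthetic archetypes and projection of a new dataset
with per-characteristic percentiles).

There is also a thin CLI:

```bash
omicschar characterize proteinGroups.txt --format maxquant --quant LFQ --out chars.json
omicschar simulate --mode batch --seed 4
omicschar fixtures --type scrna_like --seed 1 --out counts.tsv
omicschar landscape --reference reference.csv --method pca --project chars.json
```

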