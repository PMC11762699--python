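"""The 29 data characteristics of a quantitative omics matrix.

All characteristics are computed on the log2-transformed matrix with zeros
and infinities recoded as missing (see :mod:`omicschar.matrix_io`).  The
panel covers distribution shape (mean, median, extremes, variance,
skewness, kurtosis, distinct-value fraction), missingness structure
(overall and per-axis missing fractions, mean-vs-missingness correlations,
detection-threshold spread), and higher-level structure (NIPALS-PCA
variance fractions, agglomerative clustering coefficient, mean–variance
overdispersion polynomial).  Undefined characteristics (e.g. the
missingness correlations of a complete matrix) are NaN.

Expensive characteristics follow fixed subsampling rules: the
detection-threshold spreads use at most 200 randomly chosen samples, and
the clustering coefficient uses at most the 500 analytes with the fewest
missing values and at most 500 randomly chosen samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from omicschar.errors import InclusionError
from omicschar.matrix_io import (
    OmicsMatrix,
    _axis_variances,
    passes_inclusion_filters,
)
from omicschar.nipals import nipals_fit
from omicschar.errors import OmicsCharError

NAN = float("nan")

CHARACTERISTIC_NAMES: tuple[str, ...] = (
    "log2(# Samples)",
    "log2(# Analytes)",
    "Mean",
    "Median",
    "Min",
    "Max",
    "log2(Variance)",
    "median(Variance of analytes)",
    "median(Variance of samples)",
    "Kurtosis",
    "Skewness",
    "|Skewness|",
    "% Distinct values",
    "% NA",
    "min(% NA in analytes)",
    "max(% NA in analytes)",
    "min(% NA in samples)",
    "max(% NA in samples)",
    "% Analytes with NAs",
    "% Samples with NAs",
    "Corr(Mean vs. % NA) (Analytes)",
    "Corr(Mean vs. % NA) (Samples)",
    "sd(Intensity w/ prob(NA) = 50% for sample)",
    "sd(Intensity w/ prob(NA) = 90% for sample)",
    "% Var. explained by PC1",
    "% Var. explained by PC2",
    "Agglom. coef. hierarch. analyte clustering",
    "Lin. coef. of Poly2(Means vs. Vars) (Analytes)",
    "Quadr. coef. of Poly2(Means vs. Vars) (Analytes)",
)

#: Characteristics undefined whenever a matrix has no missing values; these
#: are also the ones excluded from UMAP embeddings of the landscape.
NA_DEPENDENT_CHARACTERISTICS: tuple[str, ...] = (
    "Corr(Mean vs. % NA) (Samples)",
    "Corr(Mean vs. % NA) (Analytes)",
    "sd(Intensity w/ prob(NA) = 50% for sample)",
    "sd(Intensity w/ prob(NA) = 90% for sample)",
)


@dataclass
class CharacteristicsVector:
    """One dataset's 29 named characteristic values plus provenance."""

    values: dict[str, float]
    dataset_id: str | None = None
    data_type: str | None = None
    subgroup: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(CHARACTERISTIC_NAMES) - set(self.values)
        extra = set(self.values) - set(CHARACTERISTIC_NAMES)
        if missing or extra:
            raise OmicsCharError(
                f"characteristic slots mismatch (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if not math.isnan(v)}


@dataclass
class ThresholdEstimate:
    """Per-sample intensity at which the missingness probability reaches p."""

    sample_id: str
    x50: float
    x90: float
    usable: bool
    slope: float = NAN
    converged: bool = False


def distribution_stats(matrix: OmicsMatrix) -> dict[str, float]:
    """Pooled distribution-shape characteristics plus log2 dimensions."""
    out = {
        "log2(# Samples)": math.log2(matrix.n_samples),
        "log2(# Analytes)": math.log2(matrix.n_analytes),
    }
    obs = matrix.values[~np.isnan(matrix.values)]
    if obs.size == 0:
        for name in ("Mean", "Median", "Min", "Max", "log2(Variance)",
                     "Kurtosis", "Skewness", "|Skewness|", "% Distinct values"):
            out[name] = NAN
        return out
    out["Mean"] = float(np.mean(obs))
    out["Median"] = float(np.median(obs))
    out["Min"] = float(np.min(obs))
    out["Max"] = float(np.max(obs))
    var = float(np.var(obs, ddof=1)) if obs.size >= 2 else NAN
    out["log2(Variance)"] = math.log2(var) if var and var > 0 else NAN
    # moment estimators g1 / excess g2 on the pooled observed values
    skew = float(scipy.stats.skew(obs, bias=True)) if obs.size >= 2 else NAN
    kurt = float(scipy.stats.kurtosis(obs, fisher=True, bias=True)) if obs.size >= 2 else NAN
    out["Skewness"] = skew
    out["|Skewness|"] = abs(skew) if not math.isnan(skew) else NAN
    out["Kurtosis"] = kurt
    out["% Distinct values"] = 100.0 * np.unique(obs).size / matrix.values.size
    return out


def axis_variance_medians(matrix: OmicsMatrix) -> tuple[float, float]:
    """(median per-analyte variance, median per-sample variance), each over
    rows/columns with at least two observed entries; NaN when none qualify."""
    analyte_vars = _axis_variances(matrix.values, axis=1)
    sample_vars = _axis_variances(matrix.values, axis=0)
    med_analyte = (
        float(np.nanmedian(analyte_vars)) if not np.all(np.isnan(analyte_vars)) else NAN
    )
    med_sample = (
        float(np.nanmedian(sample_vars)) if not np.all(np.isnan(sample_vars)) else NAN
    )
    return med_analyte, med_sample


def missingness_stats(matrix: OmicsMatrix) -> dict[str, float]:
    mask = matrix.missing_mask
    pct_analyte = 100.0 * mask.mean(axis=1)
    pct_sample = 100.0 * mask.mean(axis=0)
    return {
        "% NA": 100.0 * float(mask.mean()),
        "min(% NA in analytes)": float(pct_analyte.min()),
        "max(% NA in analytes)": float(pct_analyte.max()),
        "min(% NA in samples)": float(pct_sample.min()),
        "max(% NA in samples)": float(pct_sample.max()),
        "% Analytes with NAs": 100.0 * float(mask.any(axis=1).mean()),
        "% Samples with NAs": 100.0 * float(mask.any(axis=0).mean()),
    }


def missingness_mean_correlation(matrix: OmicsMatrix, axis: str) -> float:
    """Spearman correlation of per-unit %missing with per-unit observed mean.

    ``axis`` is ``"analytes"`` (rows) or ``"samples"`` (columns).  NaN when
    either variable is constant (e.g. a complete matrix) or fewer than three
    units have an observed mean.
    """
    if axis not in ("analytes", "samples"):
        raise OmicsCharError("axis must be 'analytes' or 'samples'")
    values = matrix.values if axis == "analytes" else matrix.values.T
    mask = np.isnan(values)
    pct_na = 100.0 * mask.mean(axis=1)
    counts = (~mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(values, axis=1) / np.maximum(counts, 1), np.nan)
    keep = ~np.isnan(means)
    if keep.sum() < 3:
        return NAN
    x, y = pct_na[keep], means[keep]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return NAN
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho)


def _logistic_irls(
    x: np.ndarray, y: np.ndarray, *, max_iter: int = 60, tol: float = 1e-10
) -> tuple[float, float, bool]:
    """Two-parameter logistic regression P(y=1) = logistic(b0 + b1 x) by
    Newton/IRLS with step halving.

    Under hard censoring the classes are perfectly separated and the
    unpenalized MLE diverges: the deviance keeps shrinking while the
    threshold crossing -b0/b1 stabilises in the separation gap.  The fit is
    therefore declared converged either when the deviance stalls or when
    the crossing point itself stops moving.  Returns (b0, b1, converged).
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    ybar = min(max(float(np.mean(y)), 1e-12), 1 - 1e-12)
    beta = np.array([math.log(ybar / (1 - ybar)), 0.0])

    def deviance(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -35, 35)
        return float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta))

    dev = deviance(beta)
    converged = False
    crossing_prev = math.inf
    for it in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None]) + 1e-12 * np.eye(2)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking on the deviance
        scale = 1.0
        new_dev = dev
        for _ in range(30):
            cand = beta + scale * step
            new_dev = deviance(cand)
            if new_dev <= dev + 1e-12:
                beta = cand
                break
            scale *= 0.5
        crossing = -beta[0] / beta[1] if beta[1] != 0 else math.inf
        crossing_stalled = (
            it > 3
            and math.isfinite(crossing)
            and abs(crossing - crossing_prev) <= 1e-7 * max(1.0, abs(crossing))
        )
        if (
            abs(dev - new_dev) <= tol * (abs(dev) + 1e-12)
            or new_dev < 1e-9
            or crossing_stalled
        ):
            dev = new_dev
            converged = True
            break
        dev = new_dev
        crossing_prev = crossing
    return float(beta[0]), float(beta[1]), converged


def estimate_sample_thresholds(
    matrix: OmicsMatrix, seed: int = 1, *, max_samples: int = 200
) -> list[ThresholdEstimate]:
    """Fit, per sample, a logistic missingness curve against each analyte's
    reference intensity (mean of its observed values across all samples).

    For datasets with more than ``max_samples`` samples a seeded uniform
    subset is used.  An estimate is usable only when the fit converged, the
    slope is negative (missingness rises as intensity falls) and the sample
    has both observed and missing analytes.
    """
    values = matrix.values
    mask = np.isnan(values)
    counts = (~mask).sum(axis=1)
    ref_ok = counts > 0
    with np.errstate(invalid="ignore"):
        ref = np.nansum(values, axis=1) / np.maximum(counts, 1)
    cols = np.arange(matrix.n_samples)
    if matrix.n_samples > max_samples:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(cols, size=max_samples, replace=False))
    logit50 = 0.0
    logit90 = math.log(0.9 / 0.1)
    estimates: list[ThresholdEstimate] = []
    for j in cols:
        y = mask[ref_ok, j].astype(float)
        x = ref[ref_ok]
        sid = matrix.sample_ids[j]
        if y.size < 3 or y.min() == y.max():
            estimates.append(ThresholdEstimate(sid, NAN, NAN, usable=False))
            continue
        b0, b1, converged = _logistic_irls(x, y)
        usable = converged and b1 < 0
        if usable:
            x50 = (logit50 - b0) / b1
            x90 = (logit90 - b0) / b1
        else:
            x50 = x90 = NAN
        estimates.append(
            ThresholdEstimate(sid, x50, x90, usable=usable, slope=b1, converged=converged)
        )
    return estimates


def detection_threshold_spread(
    matrix: OmicsMatrix, prob: float = 0.5, seed: int = 1
) -> float:
    """Standard deviation across samples of the intensity at which the
    per-sample missingness probability reaches ``prob`` (0.5 or 0.9).

    A large spread indicates sample-dependent detection thresholds.  NaN
    when fewer than two samples yield a usable logistic fit (in particular
    for complete matrices).
    """
    if prob not in (0.5, 0.9):
        raise OmicsCharError("prob must be 0.5 or 0.9")
    estimates = estimate_sample_thresholds(matrix, seed=seed)
    xs = [e.x50 if prob == 0.5 else e.x90 for e in estimates if e.usable]
    if len(xs) < 2:
        return NAN
    return float(np.std(xs, ddof=1))


def pca_variance_fractions(matrix: OmicsMatrix) -> tuple[float, float]:
    """Percent variance explained by the first two NIPALS principal
    components of the transposed matrix (samples as observations).

    Analytes observed in fewer than two samples carry no variance
    information and are dropped before the fit.
    """
    counts = (~np.isnan(matrix.values)).sum(axis=1)
    values = matrix.values[counts >= 2]
    if values.shape[0] < 2:
        return NAN, NAN
    try:
        result = nipals_fit(values.T, n_components=2)
    except OmicsCharError:
        return NAN, NAN
    if not all(result.converged):
        return NAN, NAN
    return float(result.var_fraction[0]), float(result.var_fraction[1])


def _pairwise_complete_distances(values: np.ndarray) -> np.ndarray | None:
    """Euclidean distances between rows over pairwise-complete coordinates,
    rescaled by sqrt(n_coords / n_shared); None if a pair shares none."""
    mask = (~np.isnan(values)).astype(float)
    A = np.nan_to_num(values, nan=0.0)
    shared = mask @ mask.T
    if np.any(shared[~np.eye(len(values), dtype=bool)] == 0):
        return None
    sq = (A**2) @ mask.T
    cross = A @ A.T
    d2 = sq + sq.T - 2.0 * cross
    np.clip(d2, 0.0, None, out=d2)
    m = values.shape[1]
    d2 *= m / shared
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def agglomerative_coefficient(
    matrix: OmicsMatrix,
    seed: int = 1,
    *,
    method: str = "average",
    max_analytes: int = 500,
    max_samples: int = 500,
) -> float:
    """Agglomerative coefficient of hierarchical clustering of analytes.

    Defined as the mean over analytes of 1 − h_first/h_final, where h_first
    is the merge height at which the analyte first joins a cluster and
    h_final the final merge height (the `agnes` banner coefficient).  Values
    near 1 indicate pronounced cluster structure.  For large matrices the
    500 analytes with the fewest missing values and a seeded subset of at
    most 500 samples are used.  NaN when all analytes coincide (h_final = 0)
    or some analyte pair shares no observed coordinate.
    """
    values = matrix.values
    if values.shape[0] < 2:
        return NAN
    if values.shape[0] > max_analytes:
        n_missing = np.isnan(values).sum(axis=1)
        keep = np.argsort(n_missing, kind="stable")[:max_analytes]
        values = values[np.sort(keep)]
    if values.shape[1] > max_samples:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(values.shape[1], size=max_samples, replace=False))
        values = values[:, cols]
    dist = _pairwise_complete_distances(values)
    if dist is None:
        return NAN
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    h_final = Z[-1, 2]
    if h_final <= 0:
        return NAN
    n = values.shape[0]
    h_first = np.full(n, np.nan)
    for left, right, height, _ in Z:
        for node in (int(left), int(right)):
            if node < n:
                h_first[node] = height
    return float(np.mean(1.0 - h_first / h_final))


def mean_variance_poly2(matrix: OmicsMatrix) -> tuple[float, float]:
    """Linear and quadratic coefficients of the OLS fit
    var_i ~ 1 + mean_i + mean_i², over analytes with ≥2 observed values.

    The pair quantifies the kind of overdispersion: a dominant linear term
    is Poisson-like scaling, a dominant quadratic term is multiplicative
    noise.  NaN pair when fewer than 3 qualifying analytes or fewer than 3
    distinct means.
    """
    variances = _axis_variances(matrix.values, axis=1)
    mask = np.isnan(matrix.values)
    counts = (~mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(matrix.values, axis=1) / np.maximum(counts, 1), np.nan)
    keep = ~np.isnan(variances) & ~np.isnan(means)
    if keep.sum() < 3 or np.unique(means[keep]).size < 3:
        return NAN, NAN
    m = means[keep]
    design = np.column_stack([np.ones(m.size), m, m**2])
    coef, *_ = np.linalg.lstsq(design, variances[keep], rcond=None)
    return float(coef[1]), float(coef[2])


def compute_all(
    matrix: OmicsMatrix,
    seed: int = 1,
    *,
    check_filters: bool = True,
) -> CharacteristicsVector:
    """Compute the full 29-characteristic panel of a preprocessed matrix.

    Deterministic given (matrix, seed); the seed drives the subsampling of
    samples for the detection-threshold and clustering characteristics.
    Raises :class:`InclusionError` when the matrix fails the inclusion
    filters (unless ``check_filters`` is disabled).
    """
    if check_filters:
        report = passes_inclusion_filters(matrix)
        if not report.passed:
            raise InclusionError(report)

    values: dict[str, float] = {}
    values.update(distribution_stats(matrix))
    med_analyte, med_sample = axis_variance_medians(matrix)
    values["median(Variance of analytes)"] = med_analyte
    values["median(Variance of samples)"] = med_sample
    values.update(missingness_stats(matrix))
    values["Corr(Mean vs. % NA) (Analytes)"] = missingness_mean_correlation(
        matrix, "analytes"
    )
    values["Corr(Mean vs. % NA) (Samples)"] = missingness_mean_correlation(
        matrix, "samples"
    )
    values["sd(Intensity w/ prob(NA) = 50% for sample)"] = detection_threshold_spread(
        matrix, 0.5, seed=seed
    )
    values["sd(Intensity w/ prob(NA) = 90% for sample)"] = detection_threshold_spread(
        matrix, 0.9, seed=seed
    )
    pc1, pc2 = pca_variance_fractions(matrix)
    values["% Var. explained by PC1"] = pc1
    values["% Var. explained by PC2"] = pc2
    values["Agglom. coef. hierarch. analyte clustering"] = agglomerative_coefficient(
        matrix, seed=seed
    )
    lin, quad = mean_variance_poly2(matrix)
    values["Lin. coef. of Poly2(Means vs. Vars) (Analytes)"] = lin
    values["Quadr. coef. of Poly2(Means vs. Vars) (Analytes)"] = quad

    return CharacteristicsVector(
        values={name: values[name] for name in CHARACTERISTIC_NAMES},
        dataset_id=matrix.dataset_id,
        data_type=matrix.data_type,
        subgroup=matrix.subgroup,
        seed=seed,
    )
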