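import math

import numpy as np
import pytest
import scipy.stats

from omicschar.characteristics import (
    CHARACTERISTIC_NAMES,
    NA_DEPENDENT_CHARACTERISTICS,
    agglomerative_coefficient,
    axis_variance_medians,
    compute_all,
    detection_threshold_spread,
    distribution_stats,
    mean_variance_poly2,
    missingness_mean_correlation,
    missingness_stats,
    pca_variance_fractions,
)
from omicschar.errors import InclusionError
from omicschar.fixtures import FixtureSpec, generate_type_fixture

from conftest import ladder_censored_matrix, make_matrix


class TestDistributionStats:
    def test_symmetric_triple(self):
        values = np.full((10, 5), np.nan)
        values[0, 0], values[1, 0], values[2, 0] = 0.0, 1.0, 2.0
        stats = distribution_stats(make_matrix(values))
        assert stats["Mean"] == 1.0
        assert stats["Median"] == 1.0
        assert stats["Min"] == 0.0
        assert stats["Max"] == 2.0
        assert stats["log2(Variance)"] == 0.0  # var of {0,1,2} is 1
        assert stats["Skewness"] == 0.0
        assert stats["log2(# Samples)"] == math.log2(5)
        assert stats["log2(# Analytes)"] == math.log2(10)

    def test_distinct_value_denominator_includes_missing(self):
        values = np.array([[5.0, 5.0], [7.0, np.nan]])
        stats = distribution_stats(make_matrix(values))
        assert stats["% Distinct values"] == 50.0  # 2 distinct / 4 cells

    def test_moment_estimators_match_scipy_on_normal_draw(self):
        rng = np.random.default_rng(123)
        draw = rng.standard_normal(50_000)
        stats = distribution_stats(make_matrix(draw.reshape(500, 100)))
        assert abs(stats["Skewness"]) < 0.1
        assert abs(stats["Kurtosis"]) < 0.1
        assert stats["Skewness"] == pytest.approx(
            float(scipy.stats.skew(draw, bias=True))
        )
        assert stats["Kurtosis"] == pytest.approx(
            float(scipy.stats.kurtosis(draw, fisher=True, bias=True))
        )

    def test_all_missing_matrix_undefined(self):
        stats = distribution_stats(make_matrix(np.full((4, 4), np.nan)))
        assert math.isnan(stats["Mean"]) and math.isnan(stats["Kurtosis"])


class TestAxisVarianceMedians:
    def test_constant_rows(self):
        values = np.tile(np.array([[3.0, 3.0]]), (5, 1))
        med_analyte, _ = axis_variance_medians(make_matrix(values))
        assert med_analyte == 0.0

    def test_known_row_variances(self):
        # row pairs [0, x] have variance x^2/2: these give variances 2, 3, 1
        values = np.array([[0, 2], [0, np.sqrt(6)], [0, np.sqrt(2)]])
        med_analyte, _ = axis_variance_medians(make_matrix(values))
        assert med_analyte == pytest.approx(2.0)

    def test_matches_bruteforce(self, sparse_matrix):
        med_analyte, med_sample = axis_variance_medians(sparse_matrix)
        values = sparse_matrix.values

        def brute(axis_values):
            out = []
            for row in axis_values:
                obs = row[~np.isnan(row)]
                if obs.size >= 2:
                    out.append(np.var(obs, ddof=1))
            return float(np.median(out)) if out else float("nan")

        assert med_analyte == pytest.approx(brute(values))
        assert med_sample == pytest.approx(brute(values.T))


class TestMissingnessStats:
    def test_small_example(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        stats = missingness_stats(make_matrix(values))
        assert stats["% NA"] == 25.0
        assert stats["min(% NA in analytes)"] == 0.0
        assert stats["max(% NA in analytes)"] == 50.0
        assert stats["% Analytes with NAs"] == 50.0
        assert stats["% Samples with NAs"] == 50.0

    def test_complete_matrix_all_zero(self, random_matrix):
        stats = missingness_stats(random_matrix)
        assert all(v == 0.0 for v in stats.values())

    def test_all_missing(self):
        stats = missingness_stats(make_matrix(np.full((10, 5), np.nan)))
        assert stats["% NA"] == 100.0
        assert stats["min(% NA in analytes)"] == 100.0
        assert stats["max(% NA in samples)"] == 100.0

    def test_na_conservation(self, sparse_matrix):
        stats = missingness_stats(sparse_matrix)
        observed = np.count_nonzero(~np.isnan(sparse_matrix.values))
        expected = 100.0 - 100.0 * observed / sparse_matrix.values.size
        assert stats["% NA"] == pytest.approx(expected)


class TestMissingnessMeanCorrelation:
    def _matrix_with_profile(self, na_mean_pairs):
        # build columns with prescribed (%NA, mean) over 10 analytes
        cols = []
        for pct, mean in na_mean_pairs:
            n_miss = int(round(pct / 10))
            col = np.full(10, float(mean))
            col[:n_miss] = np.nan
            cols.append(col)
        return make_matrix(np.column_stack(cols))

    def test_monotone_increasing(self):
        m = self._matrix_with_profile([(0, 1), (10, 2), (20, 3)])
        assert missingness_mean_correlation(m, "samples") == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        m = self._matrix_with_profile([(0, 3), (10, 2), (20, 1)])
        assert missingness_mean_correlation(m, "samples") == pytest.approx(-1.0)

    def test_complete_matrix_undefined(self, random_matrix):
        assert math.isnan(missingness_mean_correlation(random_matrix, "samples"))
        assert math.isnan(missingness_mean_correlation(random_matrix, "analytes"))


class TestDetectionThresholdSpread:
    def test_complete_matrix_undefined(self, random_matrix):
        assert math.isnan(detection_threshold_spread(random_matrix, 0.5, seed=1))

    def test_three_hard_thresholds(self):
        # dense ladder censored at exactly {2, 4, 6}
        mu = np.linspace(0.0, 8.0, 400)
        thresholds = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
        values = np.tile(mu[:, None], (1, 6)).astype(float)
        values = values + np.random.default_rng(0).normal(0, 0.05, values.shape)
        values[values < thresholds[None, :]] = np.nan
        spread = detection_threshold_spread(make_matrix(values), 0.5, seed=1)
        expected = np.std([2.0, 4.0, 6.0, 2.0, 4.0, 6.0], ddof=1)
        assert spread == pytest.approx(expected, rel=0.15)

    def test_common_threshold_near_zero_spread(self):
        mu = np.linspace(0.0, 8.0, 400)
        rng = np.random.default_rng(1)
        thresholds = 4.0 + rng.normal(0, 1e-3, size=8)
        values = np.tile(mu[:, None], (1, 8)) + rng.normal(0, 0.05, (400, 8))
        values[values < thresholds[None, :]] = np.nan
        spread = detection_threshold_spread(make_matrix(values), 0.5, seed=1)
        assert spread <= 0.1

    def test_x90_exceeds_x50_for_smooth_censoring(self):
        matrix, _ = ladder_censored_matrix(seed=3, noise_sd=0.5)
        s50 = detection_threshold_spread(matrix, 0.5, seed=1)
        s90 = detection_threshold_spread(matrix, 0.9, seed=1)
        assert s50 > 0 and s90 > 0

    def test_parameter_recovery(self):
        rels = []
        for seed in range(20):
            matrix, thresholds = ladder_censored_matrix(seed)
            est = detection_threshold_spread(matrix, 0.5, seed=1)
            rels.append(est / np.std(thresholds, ddof=1) - 1.0)
        assert abs(float(np.mean(rels))) < 0.15


class TestPcaVarianceFractions:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(4)
        values = np.outer(rng.normal(size=30), rng.normal(size=8))
        pc1, pc2 = pca_variance_fractions(make_matrix(values))
        assert pc1 == pytest.approx(100.0, abs=1e-6)
        assert pc2 == pytest.approx(0.0, abs=1e-6)

    def test_matches_svd_on_complete_data(self, random_matrix):
        pc1, pc2 = pca_variance_fractions(random_matrix)
        X = random_matrix.values.T
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        frac = 100.0 * sv**2 / np.sum(sv**2)
        assert pc1 == pytest.approx(frac[0], abs=1e-6)
        assert pc2 == pytest.approx(frac[1], abs=1e-6)

    def test_bounds_with_missing_entries(self, sparse_matrix):
        pc1, pc2 = pca_variance_fractions(sparse_matrix)
        assert 0.0 <= pc2 <= pc1 <= 100.0


class TestAgglomerativeCoefficient:
    def test_two_tight_blobs(self):
        rng = np.random.default_rng(8)
        blob1 = rng.normal(0.0, 0.05, size=(10, 6))
        blob2 = rng.normal(20.0, 0.05, size=(10, 6))
        coef = agglomerative_coefficient(make_matrix(np.vstack([blob1, blob2])))
        assert coef > 0.9

    def test_identical_analytes_undefined(self):
        values = np.tile(np.arange(6.0), (5, 1))
        assert math.isnan(agglomerative_coefficient(make_matrix(values)))

    def test_matches_naive_average_linkage(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(10, 6))
        coef = agglomerative_coefficient(make_matrix(values))
        assert coef == pytest.approx(_naive_agnes_coefficient(values), abs=1e-12)

    def test_in_unit_interval(self, sparse_matrix):
        coef = agglomerative_coefficient(sparse_matrix)
        if not math.isnan(coef):
            assert 0.0 <= coef <= 1.0


def _naive_agnes_coefficient(values: np.ndarray) -> float:
    """O(n^3) average-linkage clustering from the definition."""
    n = len(values)
    dist = {
        frozenset((i, j)): float(np.linalg.norm(values[i] - values[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    clusters = {i: [i] for i in range(n)}
    first_height = {}
    last_height = 0.0

    def cluster_distance(a, b):
        return float(
            np.mean(
                [
                    np.linalg.norm(values[i] - values[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
        )

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = cluster_distance(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for cluster in (a, b):
            if len(clusters[cluster]) == 1:
                first_height[clusters[cluster][0]] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        last_height = d
    return float(np.mean([1.0 - first_height[i] / last_height for i in range(n)]))


class TestMeanVariancePoly2:
    def _matrix_with_mean_var(self, pairs):
        # two observed values per analyte: mean m, variance v
        rows = []
        for mean, var in pairs:
            half = math.sqrt(var / 2.0)
            rows.append([mean - half, mean + half])
        return make_matrix(np.array(rows))

    def test_linear_relationship(self):
        pairs = [(m, 2.0 * m) for m in (1.0, 2.0, 3.0, 4.0)]
        lin, quad = mean_variance_poly2(self._matrix_with_mean_var(pairs))
        assert lin == pytest.approx(2.0, abs=1e-9)
        assert quad == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_relationship(self):
        pairs = [(m, m**2) for m in (1.0, 2.0, 3.0, 4.0)]
        lin, quad = mean_variance_poly2(self._matrix_with_mean_var(pairs))
        assert lin == pytest.approx(0.0, abs=1e-9)
        assert quad == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations(self, sparse_matrix):
        lin, quad = mean_variance_poly2(sparse_matrix)
        values = sparse_matrix.values
        means, variances = [], []
        for row in values:
            obs = row[~np.isnan(row)]
            if obs.size >= 2:
                means.append(np.mean(obs))
                variances.append(np.var(obs, ddof=1))
        X = np.column_stack([np.ones(len(means)), means, np.square(means)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(variances))
        assert lin == pytest.approx(beta[1], rel=1e-9)
        assert quad == pytest.approx(beta[2], rel=1e-9)

    def test_too_few_analytes_undefined(self):
        lin, quad = mean_variance_poly2(make_matrix([[1.0, 2.0], [3.0, 4.0]]))
        assert math.isnan(lin) and math.isnan(quad)


class TestComputeAll:
    def test_exactly_29_slots(self, sparse_matrix):
        vector = compute_all(sparse_matrix)
        assert len(vector.values) == 29
        assert set(vector.values) == set(CHARACTERISTIC_NAMES)

    def test_complete_matrix_undefined_slots(self):
        matrix = generate_type_fixture(FixtureSpec("microarray_like", seed=7))
        vector = compute_all(matrix)
        undefined = {k for k, v in vector.values.items() if math.isnan(v)}
        assert undefined == set(NA_DEPENDENT_CHARACTERISTICS)

    def test_deterministic(self, sparse_matrix):
        v1 = compute_all(sparse_matrix, seed=3)
        v2 = compute_all(sparse_matrix, seed=3)
        for name in CHARACTERISTIC_NAMES:
            a, b = v1.values[name], v2.values[name]
            assert (math.isnan(a) and math.isnan(b)) or a == b

    def test_refuses_failing_matrix(self):
        with pytest.raises(InclusionError) as excinfo:
            compute_all(make_matrix(np.random.default_rng(0).normal(size=(4, 4))))
        assert "min_samples" in excinfo.value.report.reasons

    def test_permutation_invariance(self, sparse_matrix):
        rng = np.random.default_rng(11)
        rows = rng.permutation(sparse_matrix.n_analytes)
        cols = rng.permutation(sparse_matrix.n_samples)
        permuted = make_matrix(sparse_matrix.values[np.ix_(rows, cols)])
        v1 = compute_all(sparse_matrix, seed=2)
        v2 = compute_all(permuted, seed=2)
        for name in CHARACTERISTIC_NAMES:
            a, b = v1.values[name], v2.values[name]
            if math.isnan(a) or math.isnan(b):
                assert math.isnan(a) and math.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-6, abs=1e-9)
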