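import numpy as np
import pandas as pd
import pytest

from omicschar.matrix_io import OmicsMatrix, RawTable


def make_matrix(values, data_type=None, subgroup=None, dataset_id=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values=values,
        analyte_ids=[f"a{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        data_type=data_type,
        subgroup=subgroup,
        dataset_id=dataset_id,
    )


def make_raw(values, row_prefix="a", col_prefix="s", source_format="generic_tsv") -> RawTable:
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"{row_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{col_prefix}{j}" for j in range(values.shape[1])],
    )
    return RawTable(frame, source_format)


def ladder_censored_matrix(seed, n_analytes=400, n_samples=20, center=18.5,
                           limit_sd=1.0, noise_sd=0.25):
    """Dense ladder of analyte intensities hard-censored at per-sample
    thresholds; returns (matrix, thresholds)."""
    rng = np.random.default_rng(seed)
    mu = np.linspace(14.0, 26.0, n_analytes)
    thresholds = rng.normal(center, limit_sd, size=n_samples)
    values = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_analytes, n_samples))
    values[values < thresholds[None, :]] = np.nan
    return make_matrix(values), thresholds


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(10.0, 2.0, size=(20, 8)))


@pytest.fixture
def sparse_matrix():
    rng = np.random.default_rng(7)
    values = rng.normal(10.0, 2.0, size=(30, 10))
    values[rng.random(values.shape) < 0.25] = np.nan
    return make_matrix(values)
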