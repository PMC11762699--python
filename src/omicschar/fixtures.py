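"""Seeded synthetic matrices emulating the hallmark characteristics of the
major omics data types.

Five archetypes are generated, each reproducing the qualitative fingerprint
its data type shows in practice rather than any particular real dataset:

* ``microarray_like`` — complete Gaussian log-intensities, no missing
  values or zeros.
* ``scrna_like`` — very sparse small-integer counts over many samples
  (cells), giving high %NA after zero conversion and a low percentage of
  distinct values.
* ``proteomics_lfq_like`` — Gaussian log2 intensities censored by
  per-sample detection thresholds, giving the positive mean-vs-%NA sample
  correlation typical of label-free quantification.
* ``metabolomics_like`` — few analytes, moderate sample counts, lognormal
  intensities with light random missingness.
* ``microbiome_16s_like`` — sparse counts with heavy-tailed taxon
  abundances.

All generators run through :func:`omicschar.matrix_io.preprocess`, so the
outputs are regular :class:`OmicsMatrix` objects on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from omicschar.errors import OmicsCharError
from omicschar.matrix_io import OmicsMatrix, RawTable, preprocess

FIXTURE_TYPES = (
    "microarray_like",
    "scrna_like",
    "proteomics_lfq_like",
    "metabolomics_like",
    "microbiome_16s_like",
)

#: default dimensions per archetype (analytes, samples), chosen to mirror
#: the relative scale of each data type while staying desk-computable
_DEFAULT_DIMS = {
    "microarray_like": (800, 16),
    "scrna_like": (2000, 300),
    "proteomics_lfq_like": (600, 16),
    "metabolomics_like": (80, 12),
    "microbiome_16s_like": (250, 40),
}


@dataclass(frozen=True)
class FixtureSpec:
    type_name: str
    n_analytes: int | None = None
    n_samples: int | None = None
    seed: int = 1

    def resolved_dims(self) -> tuple[int, int]:
        if self.type_name not in _DEFAULT_DIMS:
            raise OmicsCharError(f"unknown fixture type {self.type_name!r}")
        base = _DEFAULT_DIMS[self.type_name]
        return (
            self.n_analytes if self.n_analytes is not None else base[0],
            self.n_samples if self.n_samples is not None else base[1],
        )


def _to_matrix(
    raw: np.ndarray, spec: FixtureSpec, data_type: str, subgroup: str | None = None
) -> OmicsMatrix:
    frame = pd.DataFrame(
        raw,
        index=[f"analyte_{i}" for i in range(raw.shape[0])],
        columns=[f"sample_{j}" for j in range(raw.shape[1])],
    )
    table = RawTable(frame, "generic_tsv")
    matrix = preprocess(
        table,
        data_type=data_type,
        subgroup=subgroup,
        dataset_id=f"{spec.type_name}_seed{spec.seed}",
    )
    return matrix


def generate_type_fixture(spec: FixtureSpec) -> OmicsMatrix:
    """Generate one synthetic dataset of the requested archetype."""
    if spec.type_name not in FIXTURE_TYPES:
        raise OmicsCharError(f"unknown fixture type {spec.type_name!r}")
    n, m = spec.resolved_dims()
    rng = np.random.default_rng(spec.seed)

    if spec.type_name == "microarray_like":
        # complete matrix; raw intensities are 2**N so log2 is Gaussian
        log2_vals = rng.normal(8.0, 1.5, size=(n, m)) + rng.normal(0, 1.0, size=(n, 1))
        raw = np.exp2(log2_vals)
        return _to_matrix(raw, spec, "Microarray", "Affymetrix")

    if spec.type_name == "scrna_like":
        # gamma-poisson counts, mostly zero; cells as samples
        mean_expr = np.exp(rng.normal(-1.0, 2.0, size=(n, 1)))
        cell_depth = np.exp(rng.normal(0.0, 0.3, size=(1, m)))
        counts = rng.poisson(mean_expr * cell_depth).astype(float)
        return _to_matrix(counts, spec, "scRNA-seq (unnormalized)", "droplet-based")

    if spec.type_name == "proteomics_lfq_like":
        # log2 intensities censored at per-sample thresholds -> positive
        # sample mean vs %NA correlation
        mu = rng.normal(25.0, 3.0, size=(n, 1))
        log2_vals = mu + rng.normal(0.0, 1.0, size=(n, m))
        thresholds = rng.normal(np.percentile(log2_vals, 30), 1.5, size=m)
        log2_vals[log2_vals < thresholds[None, :]] = np.nan
        raw = np.exp2(log2_vals)
        return _to_matrix(raw, spec, "Proteomics (LFQ, PRIDE)", "Orbitrap")

    if spec.type_name == "metabolomics_like":
        mu = rng.normal(15.0, 2.5, size=(n, 1))
        log2_vals = mu + rng.normal(0.0, 1.2, size=(n, m))
        raw = np.exp2(log2_vals)
        dropout = rng.random(raw.shape) < 0.05
        raw[dropout] = np.nan
        return _to_matrix(raw, spec, "Metabolomics (MS)", "LC-(q)TOF")

    # microbiome_16s_like: heavy-tailed (lognormal-poisson) sparse counts
    abundance = np.exp(rng.normal(0.0, 2.5, size=(n, 1)))
    depth = np.exp(rng.normal(0.0, 0.4, size=(1, m)))
    counts = rng.poisson(abundance * depth * 0.3).astype(float)
    return _to_matrix(counts, spec, "Microbiome", "16S")


def generate_reference_collection(
    n_per_type: int = 8,
    seed: int = 1,
    *,
    scale: float = 0.4,
) -> list[OmicsMatrix]:
    """A seeded collection across all five archetypes with per-dataset size
    jitter, sized for landscape-level analyses.

    ``scale`` shrinks the default per-type dimensions (0.4 keeps every
    archetype's hallmark pattern while making a 5 × ``n_per_type``
    collection cheap to characterise); jitter is ±20% uniform per dataset.
    """
    if n_per_type < 1:
        raise OmicsCharError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    collection: list[OmicsMatrix] = []
    for type_name in FIXTURE_TYPES:
        base_n, base_m = _DEFAULT_DIMS[type_name]
        for k in range(n_per_type):
            jitter = rng.uniform(0.8, 1.2, size=2)
            n = max(10, int(round(base_n * scale * jitter[0])))
            m = max(5, int(round(base_m * scale * jitter[1])))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            matrix = generate_type_fixture(
                FixtureSpec(type_name, n_analytes=n, n_samples=m, seed=sub_seed)
            )
            matrix.dataset_id = f"{type_name}_{k}"
            collection.append(matrix)
    return collection
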