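"""The characteristics-based omics landscape.

A :class:`ReferenceTable` collects the characteristic vectors of many
datasets; this module provides the display transforms (log2 and rank),
per-type summaries (median and median-of-medians), between-characteristic
Spearman correlations, 2-D embeddings (NIPALS PCA, which tolerates
undefined characteristics, and UMAP, which does not), and projection of a
new dataset into a fitted embedding together with per-characteristic
percentiles — the basis of representativeness assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats

from omicschar.characteristics import (
    CHARACTERISTIC_NAMES,
    NA_DEPENDENT_CHARACTERISTICS,
    CharacteristicsVector,
)
from omicschar.errors import OmicsCharError
from omicschar.nipals import nipals_fit, project as nipals_project

#: characteristics whose display scale is log2 (the dimension and variance
#: slots are already stored on log2 scale; the two variance medians are
#: stored raw and log2-transformed for display only)
LOG2_DISPLAY = (
    "log2(# Samples)",
    "log2(# Analytes)",
    "log2(Variance)",
)
LOG2_DISPLAY_EXTRA = (
    "median(Variance of analytes)",
    "median(Variance of samples)",
)

#: characteristics shown as ranks in per-type distribution views
RANK_DISPLAY = (
    "Kurtosis",
    "Skewness",
    "Lin. coef. of Poly2(Means vs. Vars) (Analytes)",
    "Quadr. coef. of Poly2(Means vs. Vars) (Analytes)",
)

MIN_GROUP_SIZE = 5  # groups must be strictly larger than this to be retained


@dataclass
class ReferenceTable:
    """Retained characteristic vectors plus transform bookkeeping.

    ``frame`` has one row per dataset: the 29 characteristic columns plus
    ``dataset_id``, ``data_type``, ``subgroup``, ``seed``.  Original values
    are kept; transforms are applied only in views.
    """

    frame: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)
    subgroup_counts: dict[tuple[str, str | None], int] = field(default_factory=dict)

    @property
    def records(self) -> pd.DataFrame:
        return self.frame

    def characteristic_matrix(self) -> pd.DataFrame:
        return self.frame[list(CHARACTERISTIC_NAMES)]


@dataclass
class EmbeddingModel:
    """A fitted 2-D representation of the characteristics table."""

    method: str  # "pca" | "umap"
    included_characteristics: list[str]
    center: np.ndarray
    scale: np.ndarray
    reference_coordinates: np.ndarray
    reference_index: list[Any]
    seed: int
    model_state: Any = None  # NipalsResult for pca, fitted reducer for umap
    table: ReferenceTable | None = None


def _records_frame(records: list[CharacteristicsVector]) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        row = dict(rec.values)
        row["dataset_id"] = rec.dataset_id if rec.dataset_id is not None else f"dataset_{i}"
        row["data_type"] = rec.data_type
        row["subgroup"] = rec.subgroup
        row["seed"] = rec.seed
        rows.append(row)
    return pd.DataFrame(rows)


def build_reference(records: list[CharacteristicsVector]) -> ReferenceTable:
    """Assemble a reference table, dropping data-type groups with ≤ 5
    datasets and registering the log2 display transforms."""
    if not records:
        raise OmicsCharError("cannot build a reference table from zero records")
    frame = _records_frame(records)
    counts = frame["data_type"].value_counts(dropna=False)
    retained_types = [t for t, n in counts.items() if n > MIN_GROUP_SIZE]
    frame = frame[frame["data_type"].isin(retained_types)].reset_index(drop=True)
    transforms = {name: "log2" for name in LOG2_DISPLAY + LOG2_DISPLAY_EXTRA}
    group_counts = {str(t): int(counts[t]) for t in retained_types}
    sub_counts: dict[tuple[str, str | None], int] = {}
    for (t, s), n in frame.groupby(["data_type", "subgroup"], dropna=False).size().items():
        sub_counts[(str(t), None if pd.isna(s) else str(s))] = int(n)
    return ReferenceTable(
        frame=frame,
        transforms=transforms,
        group_counts=group_counts,
        subgroup_counts=sub_counts,
    )


def display_values(table: ReferenceTable) -> pd.DataFrame:
    """Characteristic matrix with registered log2 display transforms applied
    (only the raw-scale variance medians actually change)."""
    frame = table.characteristic_matrix().copy()
    for name in LOG2_DISPLAY_EXTRA:
        with np.errstate(divide="ignore", invalid="ignore"):
            col = np.log2(frame[name].to_numpy(dtype=float))
        col[~np.isfinite(col)] = np.nan
        frame[name] = col
    return frame


def rank_transform(
    table: ReferenceTable, characteristic_names: list[str] | None = None
) -> pd.DataFrame:
    """Replace the named characteristics (default: the standard rank-display
    set) by ascending average ranks across all retained datasets; undefined
    values stay undefined."""
    names = list(characteristic_names) if characteristic_names else list(RANK_DISPLAY)
    unknown = set(names) - set(CHARACTERISTIC_NAMES)
    if unknown:
        raise OmicsCharError(f"unknown characteristics: {sorted(unknown)}")
    frame = table.characteristic_matrix().copy()
    for name in names:
        frame[name] = frame[name].rank(method="average", na_option="keep")
    return frame


def summarize_by_type(table: ReferenceTable) -> pd.DataFrame:
    """Per-type medians of each characteristic plus the global
    median-of-medians row (labelled ``__global__``)."""
    if not table.group_counts:
        raise OmicsCharError("no retained groups to summarize")
    per_type = (
        table.frame.groupby("data_type", dropna=False)[list(CHARACTERISTIC_NAMES)]
        .median()
    )
    summary = per_type.copy()
    summary.loc["__global__"] = per_type.median()
    return summary


def characteristic_correlations(
    table: ReferenceTable, group: str | None = None, *, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between characteristics over
    the datasets of one data type or subgroup (or the whole table)."""
    frame = table.frame
    if group is not None:
        selected = frame[
            (frame["data_type"] == group) | (frame["subgroup"] == group)
        ]
        if selected.empty:
            raise OmicsCharError(f"unknown or empty group {group!r}")
        frame = selected
    data = frame[list(CHARACTERISTIC_NAMES)]
    corr = data.corr(method="spearman", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _standardize(
    data: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values = data.to_numpy(dtype=float)
    center = np.nanmean(values, axis=0)
    scale = np.nanstd(values, axis=0, ddof=1)
    scale = np.where((scale == 0) | np.isnan(scale), 1.0, scale)
    return (values - center) / scale, center, scale


def fit_embedding(
    table: ReferenceTable,
    method: str = "pca",
    seed: int = 1,
    *,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> EmbeddingModel:
    """Fit a 2-D embedding of the z-standardized characteristics.

    ``pca`` uses NIPALS and keeps every characteristic with at least two
    defined values, tolerating undefined entries.  ``umap`` first drops the
    four missingness-dependent characteristics (undefined for any complete
    dataset) and then any record that still has an undefined value, because
    UMAP cannot handle missing data.
    """
    if method not in ("pca", "umap"):
        raise OmicsCharError("method must be 'pca' or 'umap'")
    data = table.characteristic_matrix()
    index = table.frame["dataset_id"].tolist()

    if method == "umap":
        kept_chars = [
            c for c in CHARACTERISTIC_NAMES if c not in NA_DEPENDENT_CHARACTERISTICS
        ]
        subset = data[kept_chars]
        complete = ~subset.isna().any(axis=1)
        if complete.sum() < 3:
            raise OmicsCharError(
                "fewer than 3 complete records for UMAP; use method='pca'"
            )
        subset = subset[complete]
        z, center, scale = _standardize(subset)
        import umap  # deferred: heavy import

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, len(subset) - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        coords = np.asarray(reducer.fit_transform(z), dtype=float)
        return EmbeddingModel(
            method="umap",
            included_characteristics=kept_chars,
            center=center,
            scale=scale,
            reference_coordinates=coords,
            reference_index=[i for i, ok in zip(index, complete) if ok],
            seed=seed,
            model_state=reducer,
            table=table,
        )

    # pca: keep characteristics with >= 2 defined values (NIPALS requirement)
    kept_chars = [c for c in CHARACTERISTIC_NAMES if data[c].notna().sum() >= 2]
    subset = data[kept_chars]
    z, center, scale = _standardize(subset)
    result = nipals_fit(z, n_components=2, center=False)
    return EmbeddingModel(
        method="pca",
        included_characteristics=kept_chars,
        center=center,
        scale=scale,
        reference_coordinates=result.scores.copy(),
        reference_index=index,
        seed=seed,
        model_state=result,
        table=table,
    )


def _percentile(reference: np.ndarray, value: float) -> float:
    """Tie-stable percentile: mean of the 'less than' and 'less than or
    equal' empirical fractions, in percent."""
    ref = reference[~np.isnan(reference)]
    if ref.size == 0 or np.isnan(value):
        return float("nan")
    below = np.sum(ref < value)
    at_or_below = np.sum(ref <= value)
    return 100.0 * 0.5 * (below + at_or_below) / ref.size


def project_dataset(
    model: EmbeddingModel,
    record: CharacteristicsVector,
    group: str | None = None,
) -> dict[str, Any]:
    """Place a new dataset in a fitted embedding.

    Returns its 2-D coordinates plus, per included characteristic, the
    percentile of its value within the reference table (restricted to
    ``group`` when given).  PCA projection skips undefined entries the same
    way NIPALS does; UMAP projection requires all included characteristics
    to be defined.
    """
    values = np.array(
        [record.values[c] for c in model.included_characteristics], dtype=float
    )
    if model.method == "umap":
        if np.isnan(values).any():
            raise OmicsCharError(
                "record has undefined values among the UMAP characteristics; "
                "fit a PCA embedding instead"
            )
        z = (values - model.center) / model.scale
        coords = np.asarray(model.model_state.transform(z[None, :]), dtype=float)[0]
    else:
        z = (values - model.center) / model.scale
        coords = nipals_project(model.model_state, z)

    percentiles: dict[str, float] = {}
    if model.table is not None:
        frame = model.table.frame
        if group is not None:
            frame = frame[
                (frame["data_type"] == group) | (frame["subgroup"] == group)
            ]
            if frame.empty:
                raise OmicsCharError(f"unknown or empty group {group!r}")
        for name in model.included_characteristics:
            percentiles[name] = _percentile(
                frame[name].to_numpy(dtype=float), record.values[name]
            )
    return {
        "coordinates": np.asarray(coords, dtype=float),
        "percentiles": percentiles,
        "method": model.method,
        "group": group,
    }
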