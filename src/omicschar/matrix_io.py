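"""Reading, preprocessing and filtering of quantitative omics matrices.

All downstream statistics operate on an :class:`OmicsMatrix`: an
analyte × sample grid of log2 intensities where zeros and infinities have
been recoded as missing.  Readers exist for plain TSV matrices, MaxQuant
``proteinGroups`` tables, Expression Atlas FPKM/TPM tables whose cells hold
five comma-separated numbers, MatrixMarket sparse count matrices with
row/column label sidecar files, and microbiome taxon-abundance TSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from omicschar.errors import (
    FormatError,
    NegativeValuesError,
    OmicsCharError,
    QuantTypeError,
)

SOURCE_FORMATS = (
    "generic_tsv",
    "maxquant",
    "ea_quintuple",
    "matrixmarket",
    "microbiome_tsv",
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}

# MaxQuant per-sample column prefixes; the bare prefix (no sample name) is a
# whole-experiment summary column and is never a sample.
_MAXQUANT_PREFIXES = {
    "iBAQ": "iBAQ ",
    "Intensity": "Intensity ",
    "LFQ": "LFQ intensity ",
}


@dataclass
class RawTable:
    """A parsed but not yet preprocessed table.

    ``cells`` is a DataFrame indexed by analyte identifiers with sample
    identifiers as columns.  For ``maxquant`` tables the frame still holds
    every original column (as text) until quantification columns are
    extracted.
    """

    cells: pd.DataFrame
    source_format: str

    def __post_init__(self) -> None:
        if self.source_format not in SOURCE_FORMATS:
            raise FormatError(f"unknown source format {self.source_format!r}")
        if self.cells.index.has_duplicates:
            dupes = self.cells.index[self.cells.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate analyte identifiers: {dupes}")
        if self.cells.columns.has_duplicates:
            dupes = self.cells.columns[self.cells.columns.duplicated()][:3].tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")

    @property
    def row_labels(self) -> list[str]:
        return [str(x) for x in self.cells.index]

    @property
    def column_labels(self) -> list[str]:
        return [str(x) for x in self.cells.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape


@dataclass
class OmicsMatrix:
    """Preprocessed analyte × sample matrix of log2 intensities.

    Missing entries (original NAs, zeros, infinities) are ``NaN``.  ``values``
    is float64 with shape ``(n_analytes, n_samples)``.
    """

    values: np.ndarray
    analyte_ids: list[str]
    sample_ids: list[str]
    data_type: str | None = None
    subgroup: str | None = None
    dataset_id: str | None = None
    zeros_converted: bool = True
    log2_applied: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise OmicsCharError("matrix needs at least 1 analyte and 1 sample")
        if np.isinf(self.values).any():
            raise OmicsCharError("matrix contains infinite values after preprocessing")
        if self.values.shape != (len(self.analyte_ids), len(self.sample_ids)):
            raise OmicsCharError("label lengths do not match matrix shape")

    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.analyte_ids, columns=self.sample_ids
        )


@dataclass
class InclusionReport:
    """Outcome of the inclusion filters (minimum size and non-zero variance)."""

    passed: bool
    n_samples: int
    n_analytes: int
    total_variance: float
    median_sample_variance: float
    median_analyte_variance: float
    reasons: list[str] = field(default_factory=list)


def parse_quintuple_cell(cell: str, *, row: str = "?", column: str = "?") -> float:
    """Parse one Expression Atlas FPKM/TPM cell.

    Cells carry five comma-separated numbers summarising the within-group
    expression distribution; the third is the median and is the value used.
    A plain single number is returned as-is; empty/NA tokens map to NaN.
    """
    token = cell.strip() if isinstance(cell, str) else cell
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return float("nan")
    if isinstance(token, (int, float)):
        return float(token)
    if token in _MISSING_TOKENS:
        return float("nan")
    parts = token.split(",")
    if len(parts) == 1:
        return _parse_number(token, row=row, column=column)
    if len(parts) != 5:
        raise FormatError(
            f"cell at row {row!r}, column {column!r} has {len(parts) - 1} commas; "
            "expected 0 or 4"
        )
    return _parse_number(parts[2], row=row, column=column)


def _parse_number(token: str, *, row: str, column: str) -> float:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return float("nan")
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(
            f"non-numeric token {token!r} at row {row!r}, column {column!r}"
        ) from exc
    return value


def _numeric_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert a text frame to float, mapping only the allowed NA tokens."""
    def convert(column: pd.Series) -> pd.Series:
        return column.map(
            lambda tok: _parse_number(str(tok), row="?", column=str(column.name))
            if not isinstance(tok, (int, float))
            else float(tok)
        )

    return frame.apply(convert)


def read_matrix(
    path: str | Path,
    source_format: str = "generic_tsv",
    *,
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
) -> RawTable:
    """Read a matrix file into a :class:`RawTable`.

    Parameters
    ----------
    path:
        File to read.
    source_format:
        One of ``generic_tsv``, ``maxquant``, ``ea_quintuple``,
        ``matrixmarket``, ``microbiome_tsv``.
    rows_path, cols_path:
        Label sidecar files for ``matrixmarket`` input; default to
        ``<path>_rows`` / ``<path>_cols`` (Expression Atlas convention).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if source_format in ("generic_tsv", "microbiome_tsv"):
        frame = _read_tsv(path)
        return RawTable(_numeric_frame(frame), source_format)
    if source_format == "maxquant":
        # keep everything as text; quant columns are extracted later
        return RawTable(_read_tsv(path), "maxquant")
    if source_format == "ea_quintuple":
        frame = _read_tsv(path)
        parsed = pd.DataFrame(
            {
                col: [
                    parse_quintuple_cell(frame.at[idx, col], row=str(idx), column=str(col))
                    for idx in frame.index
                ]
                for col in frame.columns
            },
            index=frame.index,
        )
        return RawTable(parsed, "ea_quintuple")
    if source_format == "matrixmarket":
        return _read_matrixmarket(path, rows_path, cols_path)
    raise FormatError(f"unknown source format {source_format!r}")


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            dtype=str,
            keep_default_na=False,
            on_bad_lines="error",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path} has no sample columns")
    return frame


def _read_matrixmarket(
    path: Path, rows_path: str | Path | None, cols_path: str | Path | None
) -> RawTable:
    rows_path = Path(rows_path) if rows_path else Path(str(path) + "_rows")
    cols_path = Path(cols_path) if cols_path else Path(str(path) + "_cols")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise FormatError(f"missing MatrixMarket label sidecar: {side}")
    try:
        sparse = scipy.io.mmread(path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    dense = np.asarray(
        sparse.todense() if scipy.sparse.issparse(sparse) else sparse, dtype=float
    )
    row_labels = _read_labels(rows_path)
    col_labels = _read_labels(cols_path)
    if dense.shape != (len(row_labels), len(col_labels)):
        raise FormatError(
            f"label sidecars ({len(row_labels)}×{len(col_labels)}) do not match "
            f"matrix shape {dense.shape}"
        )
    frame = pd.DataFrame(dense, index=row_labels, columns=col_labels)
    return RawTable(frame, "matrixmarket")


def _read_labels(path: Path) -> list[str]:
    # sidecars are one label per line; tab-separated lines keep the first field
    labels = []
    for line in path.read_text().splitlines():
        if line.strip():
            labels.append(line.split("\t")[0].strip())
    return labels


def extract_maxquant_columns(table: RawTable, quant_type: str) -> RawTable:
    """Select the per-sample quantification columns of one MaxQuant family.

    ``quant_type`` is ``iBAQ``, ``Intensity`` or ``LFQ``.  The bare summary
    column whose header is exactly the prefix (e.g. ``iBAQ``) is a
    whole-experiment total and is excluded; sample labels are the header
    remainders after the prefix.
    """
    if quant_type not in _MAXQUANT_PREFIXES:
        raise QuantTypeError(
            f"quant_type must be one of {sorted(_MAXQUANT_PREFIXES)}, got {quant_type!r}"
        )
    prefix = _MAXQUANT_PREFIXES[quant_type]
    picked = {
        col: col[len(prefix):]
        for col in table.cells.columns
        if isinstance(col, str) and col.startswith(prefix) and col != prefix.strip()
    }
    if not picked:
        raise QuantTypeError(
            f"no per-sample {quant_type!r} columns found "
            f"(looked for headers starting with {prefix!r})"
        )
    frame = table.cells[list(picked)].rename(columns=picked)
    return RawTable(_numeric_frame(frame), table.source_format)


def preprocess(
    table: RawTable,
    *,
    data_type: str | None = None,
    subgroup: str | None = None,
    dataset_id: str | None = None,
    log2: bool = True,
) -> OmicsMatrix:
    """Convert a RawTable into an :class:`OmicsMatrix`.

    Zeros and infinities become missing, then the remaining values are
    log2-transformed.  Matrices holding strictly negative values are
    rejected: negatives indicate an upstream log transformation, after which
    the shared preprocessing would be wrong.
    """
    values = table.cells.to_numpy(dtype=float).copy()
    values[np.isinf(values)] = np.nan
    values[values == 0] = np.nan
    if np.nanmin(values, initial=np.inf) < 0:
        raise NegativeValuesError(
            "matrix contains negative values (data may already be log-transformed)"
        )
    if log2:
        observed = ~np.isnan(values)
        values[observed] = np.log2(values[observed])
    return OmicsMatrix(
        values=values,
        analyte_ids=table.row_labels,
        sample_ids=table.column_labels,
        data_type=data_type,
        subgroup=subgroup,
        dataset_id=dataset_id,
        zeros_converted=True,
        log2_applied=log2,
    )


def _axis_variances(values: np.ndarray, axis: int) -> np.ndarray:
    """Per-row (axis=1) or per-column (axis=0) variances over observed
    entries, NaN where fewer than 2 observations."""
    mask = ~np.isnan(values)
    counts = mask.sum(axis=axis)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(values, axis=axis)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        centered = values - np.expand_dims(means, axis)
        ss = np.nansum(centered**2, axis=axis)
        variances = np.where(counts >= 2, ss / np.maximum(counts - 1, 1), np.nan)
    return variances


def passes_inclusion_filters(
    matrix: OmicsMatrix,
    *,
    min_samples: int = 5,
    min_analytes: int = 10,
) -> InclusionReport:
    """Check minimum size and non-zero variance requirements.

    A dataset qualifies when it has at least 5 samples, at least 10 analytes,
    and total variance, median per-sample variance and median per-analyte
    variance all strictly positive (each computed on observed values).
    """
    reasons: list[str] = []
    observed = matrix.values[~np.isnan(matrix.values)]
    total_var = float(np.var(observed, ddof=1)) if observed.size >= 2 else 0.0

    analyte_vars = _axis_variances(matrix.values, axis=1)
    sample_vars = _axis_variances(matrix.values, axis=0)
    med_analyte = (
        float(np.nanmedian(analyte_vars)) if not np.all(np.isnan(analyte_vars)) else 0.0
    )
    med_sample = (
        float(np.nanmedian(sample_vars)) if not np.all(np.isnan(sample_vars)) else 0.0
    )

    if matrix.n_samples < min_samples:
        reasons.append("min_samples")
    if matrix.n_analytes < min_analytes:
        reasons.append("min_analytes")
    if not total_var > 0:
        reasons.append("zero_variance_total")
    if not med_sample > 0:
        reasons.append("zero_variance_samples")
    if not med_analyte > 0:
        reasons.append("zero_variance_analytes")

    return InclusionReport(
        passed=not reasons,
        n_samples=matrix.n_samples,
        n_analytes=matrix.n_analytes,
        total_variance=total_var,
        median_sample_variance=med_sample,
        median_analyte_variance=med_analyte,
        reasons=reasons,
    )


def _fingerprint(matrix: OmicsMatrix) -> tuple:
    """Content fingerprint invariant to row/column permutation with labels."""
    row_order = np.argsort(np.asarray(matrix.analyte_ids, dtype=object), kind="stable")
    col_order = np.argsort(np.asarray(matrix.sample_ids, dtype=object), kind="stable")
    canon = matrix.values[np.ix_(row_order, col_order)]
    mask = np.isnan(canon)
    return (
        canon.shape,
        np.nan_to_num(canon, nan=0.0).tobytes(),
        mask.tobytes(),
    )


def deduplicate(collection: list[OmicsMatrix]) -> list[OmicsMatrix]:
    """Drop content-duplicate matrices (same values and missingness after
    canonical label ordering), keeping the first occurrence."""
    seen: set[tuple] = set()
    survivors: list[OmicsMatrix] = []
    for matrix in collection:
        key = _fingerprint(matrix)
        if key not in seen:
            seen.add(key)
            survivors.append(matrix)
    return survivors
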