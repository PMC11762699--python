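"""Registry of supported omics data types and their subgroups.

Each top-level data type corresponds to one source-file convention
(file-name pattern plus repository of origin).  MaxQuant proteomics tables
are analysed once per quantification column family (iBAQ, Intensity, LFQ),
so each family is its own data type.  Subgroups refine a data type by an
acquisition attribute: chromatography and mass-spectrometer technology for
metabolomics/lipidomics, MS instrument for PRIDE proteomics, array
manufacturer for microarrays, library technology for scRNA-seq, and
sequencing strategy (16S amplicon vs whole-genome shotgun) for microbiome
data.  Data types without a finer split count as a single subgroup of
their own.
"""

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DataTypeEntry:
    name: str
    database: str
    file_pattern: str
    source_format: str  # reader tag in matrix_io
    quant_type: str | None = None  # MaxQuant column family, where applicable
    subgroups: tuple[str, ...] = field(default_factory=tuple)


_PRIDE_INSTRUMENTS = ("Orbitrap", "Q Exactive", "maXis", "TripleTOF", "timsTOF")
_SC_TECHNOLOGIES = ("droplet-based", "SMART-like")

DATA_TYPES: tuple[DataTypeEntry, ...] = (
    DataTypeEntry(
        "Metabolomics (NMR)", "MetaboLights", r"^m_.*\.tsv$ (name contains 'NMR')",
        "generic_tsv",
    ),
    DataTypeEntry(
        "Metabolomics (MS)", "MetaboLights", r"^m_.*\.tsv$ (name without 'NMR')",
        "generic_tsv",
        subgroups=("GC-(q)TOF", "LC-(q)TOF", "LC-LTQ", "LC-TQ", "LC-Q"),
    ),
    DataTypeEntry(
        "Lipidomics (MS)", "MetaboLights", r"^m_.*\.tsv$ (name without 'NMR')",
        "generic_tsv",
        subgroups=("GC-(q)TOF", "LC-(q)TOF", "LC-LTQ"),
    ),
    DataTypeEntry(
        "Proteomics (iBAQ, PRIDE)", "PRIDE", "proteinGroups", "maxquant",
        quant_type="iBAQ", subgroups=_PRIDE_INSTRUMENTS,
    ),
    DataTypeEntry(
        "Proteomics (Intensity, PRIDE)", "PRIDE", "proteinGroups", "maxquant",
        quant_type="Intensity", subgroups=_PRIDE_INSTRUMENTS,
    ),
    DataTypeEntry(
        "Proteomics (LFQ, PRIDE)", "PRIDE", "proteinGroups", "maxquant",
        quant_type="LFQ", subgroups=_PRIDE_INSTRUMENTS,
    ),
    DataTypeEntry(
        "Proteomics (iBAQ, Expression Atlas)", "Expression Atlas",
        "-proteinGroups.txt$", "maxquant", quant_type="iBAQ",
    ),
    DataTypeEntry(
        "Proteomics (Intensity, Expression Atlas)", "Expression Atlas",
        "-proteinGroups.txt$", "maxquant", quant_type="Intensity",
    ),
    DataTypeEntry(
        "scProteomics", "scpdata", "(R package snapshot)", "generic_tsv",
    ),
    DataTypeEntry(
        "Microarray", "Expression Atlas", "-normalized-expressions.tsv$",
        "generic_tsv", subgroups=("Affymetrix", "Agilent"),
    ),
    DataTypeEntry(
        "RNA-seq (raw)", "Expression Atlas",
        "-raw-counts.tsv(.undecorated)?$", "generic_tsv",
    ),
    DataTypeEntry(
        "RNA-seq (FPKM)", "Expression Atlas", "-fpkms.tsv$", "ea_quintuple",
    ),
    DataTypeEntry(
        "RNA-seq (TPM)", "Expression Atlas", "-tpms.tsv$", "ea_quintuple",
    ),
    DataTypeEntry(
        "scRNA-seq (unnormalized)", "Single Cell Expression Atlas",
        ".aggregated_filtered_counts.mtx$", "matrixmarket",
        subgroups=_SC_TECHNOLOGIES,
    ),
    DataTypeEntry(
        "scRNA-seq (normalized)", "Single Cell Expression Atlas",
        ".aggregated_filtered_normalised_counts.mtx$", "matrixmarket",
        subgroups=_SC_TECHNOLOGIES,
    ),
    DataTypeEntry(
        "Microbiome", "MicrobiomeDB", "taxon_abundance.tsv$", "microbiome_tsv",
        subgroups=("16S", "WGS"),
    ),
)

# A data type without a finer split is itself one subgroup.
SUBGROUPS: dict[str, tuple[str, ...]] = {
    entry.name: entry.subgroups if entry.subgroups else (entry.name,)
    for entry in DATA_TYPES
}


def data_type_names() -> list[str]:
    """Names of all registered top-level data types."""
    return [entry.name for entry in DATA_TYPES]


def subgroup_names() -> list[str]:
    """Flat '<type> / <subgroup>' labels across the whole registry."""
    return [
        f"{type_name} / {sub}"
        for type_name, subs in SUBGROUPS.items()
        for sub in subs
    ]


def get_entry(name: str) -> DataTypeEntry:
    for entry in DATA_TYPES:
        if entry.name == name:
            return entry
    raise KeyError(f"unknown data type: {name!r}")
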