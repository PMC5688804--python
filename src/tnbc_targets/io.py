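"""Readers and writers for every table the pipeline touches.

All tabular formats are UTF-8 TSV with a header row; CpG islands are BED3.
Genomic coordinates are 0-based, half-open (BED convention) throughout, and
a transcription start site (TSS) is a single base position in that system.
Enum-like columns are parsed case-insensitively; unknown tokens are errors,
never silently treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("tnbc_targets")

#: Recognised unit tags for an :class:`ExpressionMatrix`.
UNITS = frozenset(
    {
        "counts",
        "uq_normalized",
        "log2p1_uq",
        "beta",
        "m_value",
        "quantile_normalized",
        "log_abundance",
    }
)

#: Units whose values must be non-negative.
_NONNEG_UNITS = frozenset({"counts", "uq_normalized", "log2p1_uq", "beta"})

_MISSING_TOKENS = frozenset({"", "missing", "na", "nan", "none"})


class TableFormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass
class ExpressionMatrix:
    """A genes-by-samples value matrix with a unit tag.

    ``data`` has gene ids as the index and sample ids as columns. The unit
    tag records where the matrix sits in the transform graph
    (counts -> uq_normalized -> log2p1_uq; beta <-> m_value).
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise TableFormatError(f"unknown unit tag {self.unit!r}; expected one of {sorted(UNITS)}")
        self.data = self.data.rename_axis(index="gene_id", columns=None)
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise TableFormatError("expression matrix contains non-finite values")
        if self.unit in _NONNEG_UNITS and values.size and (values < 0).any():
            raise TableFormatError(f"negative values are not allowed for unit {self.unit!r}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what}(s): {dup[:5]}")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)


def read_matrix(path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes-by-samples TSV matrix (first column gene ids)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: matrix needs a gene-id column plus >=1 sample column")
    gene_col = raw.columns[0]
    frame = raw.set_index(gene_col)
    columns = {}
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & (frame[col].str.strip() != "")
        if bad.any():
            row = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise TableFormatError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
        if converted.isna().any():
            row = frame.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise TableFormatError(f"{path}: empty cell at gene {row!r}, sample {col!r}")
        columns[col] = converted
    matrix = ExpressionMatrix(pd.concat(columns, axis=1), unit=unit)
    log.debug("read matrix %s: %d genes x %d samples (%s)", path, *matrix.shape, unit)
    return matrix


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def _fold_enum(series: pd.Series, allowed: frozenset[str], column: str, *, allow_missing: bool) -> pd.Series:
    folded = series.str.strip().str.lower()
    if allow_missing:
        folded = folded.where(~folded.isin(_MISSING_TOKENS), "missing")
    bad = ~folded.isin(allowed)
    if bad.any():
        token = series[bad].iloc[0]
        raise TableFormatError(f"unknown token {token!r} in column {column!r}; expected {sorted(allowed)}")
    return folded


IHC_COLUMNS = ("ihc_er", "ihc_pr", "ihc_her2")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet.

    Required columns: ``sample_id`` and ``tissue_class`` (tumor/normal).
    Optional: the three IHC receptor labels (pos/neg/missing; absent columns
    default to all-missing) and ``cohort`` (tissue/cell_line, default tissue).
    """
    sheet = _read_tsv(path)
    for required in ("sample_id", "tissue_class"):
        if required not in sheet.columns:
            raise TableFormatError(f"{path}: sample sheet lacks required column {required!r}")
    _check_unique(pd.Index(sheet["sample_id"]), "sample id")
    sheet["tissue_class"] = _fold_enum(
        sheet["tissue_class"], frozenset({"tumor", "normal"}), "tissue_class", allow_missing=False
    )
    for col in IHC_COLUMNS:
        if col in sheet.columns:
            sheet[col] = _fold_enum(
                sheet[col], frozenset({"pos", "neg", "missing"}), col, allow_missing=True
            )
        else:
            sheet[col] = "missing"
    if "cohort" in sheet.columns:
        sheet["cohort"] = _fold_enum(
            sheet["cohort"], frozenset({"tissue", "cell_line"}), "cohort", allow_missing=False
        )
    else:
        sheet["cohort"] = "tissue"
    return sheet[["sample_id", "tissue_class", *IHC_COLUMNS, "cohort"]]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_islands(path: str | Path) -> pd.DataFrame:
    """Read CpG islands from BED3 (0-based, half-open intervals)."""
    islands = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if (islands["start"] < 0).any():
        raise TableFormatError(f"{path}: negative interval coordinate")
    bad = islands["end"] <= islands["start"]
    if bad.any():
        row = islands[bad].iloc[0]
        raise TableFormatError(
            f"{path}: interval with end <= start ({row.chrom}:{row.start}-{row.end})"
        )
    return islands


def write_islands(islands: pd.DataFrame, path: str | Path) -> None:
    islands[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table: gene_id, chrom, tss (0-based), strand.

    Strand is carried through but only the TSS coordinate it locates is used;
    no strand arithmetic is performed anywhere in the pipeline.
    """
    genes = _read_tsv(path)
    for required in ("gene_id", "chrom", "tss", "strand"):
        if required not in genes.columns:
            raise TableFormatError(f"{path}: gene annotation lacks column {required!r}")
    _check_unique(pd.Index(genes["gene_id"]), "gene id")
    genes["tss"] = pd.to_numeric(genes["tss"], errors="raise").astype(np.int64)
    if (genes["tss"] < 0).any():
        raise TableFormatError(f"{path}: negative TSS coordinate")
    genes["strand"] = _fold_enum(genes["strand"], frozenset({"+", "-", "."}), "strand", allow_missing=False)
    return genes[["gene_id", "chrom", "tss", "strand"]]


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _fold_bool(series: pd.Series, column: str) -> pd.Series:
    folded = series.str.strip().str.lower()
    bad = ~folded.isin(_BOOL_TOKENS)
    if bad.any():
        token = series[bad].iloc[0]
        raise TableFormatError(f"unknown boolean token {token!r} in column {column!r}")
    return folded.map(_BOOL_TOKENS)


def read_target_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-gene druggability annotations.

    Columns: gene_id, pub_count (non-negative int), has_structure,
    structure_druggable (booleans), ligand_percentile (0-100 or empty for
    missing).
    """
    table = _read_tsv(path)
    required = ("gene_id", "pub_count", "has_structure", "structure_druggable", "ligand_percentile")
    for col in required:
        if col not in table.columns:
            raise TableFormatError(f"{path}: target annotation lacks column {col!r}")
    _check_unique(pd.Index(table["gene_id"]), "gene id")
    table["pub_count"] = pd.to_numeric(table["pub_count"], errors="raise").astype(np.int64)
    if (table["pub_count"] < 0).any():
        raise TableFormatError(f"{path}: negative publication count")
    for col in ("has_structure", "structure_druggable"):
        table[col] = _fold_bool(table[col], col)
    percentile = table["ligand_percentile"].str.strip()
    table["ligand_percentile"] = pd.to_numeric(percentile.replace("", np.nan), errors="raise")
    valid = table["ligand_percentile"].dropna()
    if ((valid < 0) | (valid > 100)).any():
        raise TableFormatError(f"{path}: ligand_percentile outside [0, 100]")
    return table[list(required)]


def write_target_annotations(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a methylation probe table.

    Layout: probe_id, chrom, pos (0-based), then one beta-value column per
    sample. Returns ``(meta, beta)`` where ``meta`` holds probe coordinates
    and ``beta`` is probes x samples, both indexed by probe id.
    """
    table = _read_tsv(path)
    for required in ("probe_id", "chrom", "pos"):
        if required not in table.columns:
            raise TableFormatError(f"{path}: probe table lacks column {required!r}")
    _check_unique(pd.Index(table["probe_id"]), "probe id")
    table = table.set_index("probe_id")
    meta = table[["chrom", "pos"]].copy()
    meta["pos"] = pd.to_numeric(meta["pos"], errors="raise").astype(np.int64)
    if (meta["pos"] < 0).any():
        raise TableFormatError(f"{path}: negative probe coordinate")
    sample_cols = [c for c in table.columns if c not in ("chrom", "pos")]
    if not sample_cols:
        raise TableFormatError(f"{path}: probe table has no sample columns")
    beta = table[sample_cols].apply(pd.to_numeric, errors="raise")
    if ((beta <= 0) | (beta >= 1)).to_numpy().any():
        raise TableFormatError(f"{path}: beta values must lie strictly inside (0, 1)")
    return meta, beta


def write_probe_table(meta: pd.DataFrame, beta: pd.DataFrame, path: str | Path) -> None:
    if not meta.index.equals(beta.index):
        raise TableFormatError("probe meta and beta tables must share the same probe index")
    pd.concat([meta[["chrom", "pos"]], beta], axis=1).to_csv(path, sep="\t", index_label="probe_id")
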