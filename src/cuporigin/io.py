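"""Tab-delimited input/output for expression matrices and sample tables.

The on-disk dialect is deliberately plain: an expression matrix is a
TSV with probe identifiers in the first column and one column per
sample (log2 scale); sample and probe tables are TSVs indexed by their
first column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

GROUPS = ("primary", "metastasis", "CUP", "normal")
SEXES = ("M", "F", "unknown")


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique ids, finite float values."""
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate probe identifier {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier {dup!r}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probes x samples expression matrix from TSV."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return validate_matrix(matrix.astype(float))


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample table (sample_id, class_label, group, sex) from TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_samples(table)


def validate_samples(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier {dup!r}")
    required = {"class_label", "group", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sample table lacks columns: {sorted(missing)}")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown sample group(s): {sorted(bad_group)}")
    bad_sex = set(table["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex value(s): {sorted(bad_sex)}")
    return table


def write_samples(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path: str | os.PathLike) -> pd.Series:
    """Read a probe -> gene symbol table (TSV: probe_id, gene_symbol)."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "gene_symbol" not in table.columns:
        raise ValueError("annotation table lacks a 'gene_symbol' column")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"probe {dup!r} annotated more than once")
    return table["gene_symbol"]


def write_annotation(annotation: pd.Series, path: str | os.PathLike) -> None:
    annotation.rename("gene_symbol").to_csv(path, sep="\t", index_label="probe_id")


def align(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Return the sample table reindexed to the matrix columns.

    Raises if the two disagree on the sample set.
    """
    if set(matrix.columns) != set(samples.index):
        extra = sorted(set(matrix.columns) ^ set(samples.index))[:5]
        raise ValueError(f"matrix and sample table disagree on samples, e.g. {extra}")
    return samples.loc[matrix.columns]
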