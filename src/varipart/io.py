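"""Delimited-text readers and writers.

Expression and weight matrices are genes × samples with a header row of
sample ids and gene ids in the first column; metadata is samples × columns
with the sample id in the first (or a named) column.  The delimiter is
sniffed from the extension (.tsv/.txt → tab, otherwise comma).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


read_weights = read_expression


def read_metadata(path, sample_col: str | None = None,
                  column_types: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a metadata table; numeric columns become continuous covariates.

    ``column_types`` optionally forces columns to ``"categorical"`` or
    ``"continuous"`` regardless of the inferred dtype.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    if sample_col is None:
        sample_col = df.columns[0]
    df = df.set_index(sample_col)
    df.index = df.index.astype(str)
    for col, kind in (column_types or {}).items():
        if kind == "categorical":
            df[col] = df[col].astype(str)
        elif kind == "continuous":
            df[col] = pd.to_numeric(df[col])
        else:
            raise ValueError(f"unknown column type {kind!r} for '{col}'")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path))


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
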