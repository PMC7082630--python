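"""Tab-separated readers and writers for all pipeline tables.

Everything on disk is plain TSV with explicit tidy columns.  Missing
values are empty fields — never zeros, because zero is a meaningful
abundance in ratio computations.  Floats are written with ``%.10g`` so
that write -> read round-trips are lossless for practical purposes and
repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tpp import TemperatureGrid

__all__ = [
    "TableFormatError",
    "read_tpp_table",
    "write_tpp_table",
    "read_expression_table",
    "write_expression_table",
    "read_redox_table",
    "write_redox_table",
    "write_table",
    "read_table",
]

FLOAT_FORMAT = "%.10g"


class TableFormatError(ValueError):
    """A TSV does not conform to the expected dialect."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy frame as TSV (empty string for missing values)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")


def _reject_duplicates(df: pd.DataFrame, key: list[str], path) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.values)[0]) + 2  # 1-based incl. header
        raise TableFormatError(
            f"{path}: duplicate {tuple(key)} key at line {row}"
        )


def read_tpp_table(path: str | Path) -> tuple[pd.DataFrame, TemperatureGrid]:
    """Read a wide TPP abundance table and recover its temperature grid.

    Expected header: protein_id, condition, replicate, then one column
    per temperature whose name is the numeric degC value.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein_id", "condition", "replicate"], path)
    temp_cols = [c for c in df.columns if c not in ("protein_id", "condition", "replicate")]
    if not temp_cols:
        raise TableFormatError(f"{path}: no temperature columns found")
    try:
        temps = [float(c) for c in temp_cols]
    except ValueError as err:
        raise TableFormatError(
            f"{path}: non-numeric temperature column header ({err})"
        ) from None
    try:
        grid = TemperatureGrid(tuple(temps))
    except ValueError as err:
        raise TableFormatError(f"{path}: bad temperature grid: {err}") from None
    _reject_duplicates(df, ["protein_id", "condition", "replicate"], path)
    for col in temp_cols:
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] < 0).any():
            raise TableFormatError(f"{path}: negative abundance in column {col}")
    return df, grid


def write_tpp_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy expression table; non-positive intensities are dropped
    with a warning (they cannot enter a log fold change)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["protein_id", "cell_line", "treatment", "replicate", "intensity"], path
    )
    _reject_duplicates(df, ["protein_id", "cell_line", "treatment", "replicate"], path)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    bad = df["intensity"] <= 0
    if bad.any():
        import logging

        logging.getLogger(__name__).warning(
            "%s: dropping %d rows with non-positive intensity", path, int(bad.sum())
        )
        df = df[~bad].reset_index(drop=True)
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def read_redox_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy redox label-pair table (label columns may be empty =
    missing, but never negative)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df,
        ["peptide_id", "protein_id", "condition", "replicate",
         "label1_abundance", "label2_abundance"],
        path,
    )
    _reject_duplicates(df, ["peptide_id", "condition", "replicate"], path)
    for col in ("label1_abundance", "label2_abundance"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] < 0).any():
            row = int(np.flatnonzero((df[col] < 0).values)[0]) + 2
            raise TableFormatError(
                f"{path}: negative abundance in column {col} at line {row}"
            )
    return df


def write_redox_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)
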