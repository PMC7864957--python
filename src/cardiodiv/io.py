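"""Delimited-table readers and writers for the pipeline's data contracts.

Hemisegment tables are one row per scored hemisegment; Ct tables are one
row per qPCR replicate.  The delimiter is inferred from the extension
(``.tsv`` -> tab, anything else -> comma).  Validation failures name the
offending column and 1-based data row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

HEMISEGMENT_COLUMNS = (
    "embryo_id",
    "genotype",
    "hemisegment_index",
    "tin_cc",
    "svp_cc",
    "svp_pc",
    "enlarged_svp_cc",
)

CT_COLUMNS = ("condition", "gene", "replicate", "ct")

_TRUTHY = {"true", "1", "t", "yes"}
_FALSY = {"false", "0", "f", "no"}


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _require_columns(df: pd.DataFrame, required, path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_bool(series: pd.Series, name: str, path: Path) -> pd.Series:
    as_str = series.astype(str).str.strip().str.lower()
    bad = ~(as_str.isin(_TRUTHY) | as_str.isin(_FALSY))
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: column {name} row {row}: {series[bad.idxmax()]!r} "
            "is not a boolean (use true/false or 1/0)"
        )
    return as_str.isin(_TRUTHY)


def _parse_int(series: pd.Series, name: str, path: Path, minimum: int = 0) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < minimum)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: column {name} row {row}: {series[bad.idxmax()]!r} "
            f"is not an integer >= {minimum}"
        )
    return numeric.astype(int)


def read_hemisegment_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a hemisegment count table (.csv or .tsv)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, skipinitialspace=True)
    _require_columns(df, HEMISEGMENT_COLUMNS, path)
    df = df.loc[:, list(HEMISEGMENT_COLUMNS)].copy()
    for col in ("hemisegment_index", "tin_cc", "svp_cc", "svp_pc"):
        df[col] = _parse_int(df[col], col, path)
    df["enlarged_svp_cc"] = _parse_bool(df["enlarged_svp_cc"], "enlarged_svp_cc", path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as delimited text, delimiter chosen by extension."""
    path = Path(path)
    df.to_csv(path, sep=_sep(path), index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a qPCR Ct table (.csv or .tsv)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, skipinitialspace=True)
    _require_columns(df, CT_COLUMNS, path)
    df = df.loc[:, list(CT_COLUMNS)].copy()
    numeric = pd.to_numeric(df["ct"], errors="coerce")
    if numeric.isna().any():
        row = int(numeric.isna().idxmax()) + 1
        raise SchemaError(f"{path}: column ct row {row} is not numeric")
    df["ct"] = numeric.astype(float)
    return df
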