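"""Packaged table transcriptions and exact summary operations over them.

The tables are shipped verbatim as TSV under ``fixtures/data``; numeric
cells keep their printed precision (including "0.010", which a strict "<"
at threshold 0.01 must exclude). table1 carries 27 module rows plus the
"M0 (unassigned genes)" row; tables 3-5 carry 28 gene rows each.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TABLE_NAMES = ("table1", "table2", "table3", "table4", "table5")

_UNASSIGNED_LABEL = "M0"


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged tables (table1..table5) as a DataFrame."""
    if name not in TABLE_NAMES:
        raise ValueError(f"unknown table: {name!r} (expected one of {TABLE_NAMES})")
    ref = resources.files("netpres.fixtures").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _module_rows(t: pd.DataFrame, include_unassigned: bool) -> pd.DataFrame:
    if "Modules" in t.columns and not include_unassigned:
        is_m0 = t["Modules"].str.split().str[0] == _UNASSIGNED_LABEL
        return t[~is_m0]
    return t


def table_column_summary(
    t: pd.DataFrame,
    column: str,
    stat: str,
    include_unassigned: bool = False,
) -> float:
    """min/max/mean/sum of a numeric column (M0 row excluded by default)."""
    if column not in t.columns:
        raise KeyError(f"unknown column: {column!r}")
    rows = _module_rows(t, include_unassigned)
    values = pd.to_numeric(rows[column])
    if stat == "min":
        return float(values.min())
    if stat == "max":
        return float(values.max())
    if stat == "mean":
        return float(values.mean())
    if stat == "sum":
        return float(values.sum())
    raise ValueError(f"unknown stat: {stat!r}")


def count_below(t: pd.DataFrame, column: str, threshold: float) -> int:
    """Number of rows with value strictly below ``threshold``."""
    if column not in t.columns:
        raise KeyError(f"unknown column: {column!r}")
    values = pd.to_numeric(t[column])
    return int((values < threshold).sum())


def gene_list(t: pd.DataFrame, module: str, pathway: str) -> list[str]:
    """Comma-separated gene symbols of one table2 row."""
    rows = t[(t["Preserved Module"] == module) & (t["Pathway"] == pathway)]
    if rows.empty:
        raise KeyError(f"no row for module={module!r}, pathway={pathway!r}")
    cell = rows.iloc[0]["Genes"]
    return [g.strip() for g in str(cell).split(",") if g.strip()]
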