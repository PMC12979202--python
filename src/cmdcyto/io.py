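"""Delimited-text I/O for cells and slides tables.

Fixed schemas:

* cells — ``slide_id, cell_id, x, y, z, [true_class], cmd_<class>...,
  [label]``;
* slides — ``slide_id, centre, prep, diagnosis, age, hpv,
  [count_<class>...]``.

A thin column-mapping option adapts externally deposited dialects (renaming
only) without code changes.  Category values are validated on load and
rejected with row numbers; missing HPV results map to the ``missing`` level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .taxonomy import BETHESDA_CATEGORIES, HPV_LEVELS, PREP_METHODS

SLIDE_REQUIRED = ["slide_id", "centre", "prep", "diagnosis", "age", "hpv"]
CELL_REQUIRED = ["slide_id", "cell_id", "x", "y", "z"]

_HPV_ALIASES = {
    "positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "0": "negative",
    "missing": "missing", "n/a": "missing", "na": "missing", "": "missing",
    "nan": "missing",
}


class SchemaError(ValueError):
    """A table failed schema validation; the message names file/column/rows."""


def _apply_mapping(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=column_map)
    return df


def load_slides(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a slides table; unknown categories are rejected."""
    df = _apply_mapping(pd.read_csv(path, comment="#"), column_map)
    missing = [c for c in SLIDE_REQUIRED if c not in df.columns and c != "hpv"]
    if missing:
        raise SchemaError(f"{path}: slides table missing columns {missing}")
    bad = df.loc[~df["diagnosis"].isin(BETHESDA_CATEGORIES)]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown Bethesda categories "
            f"{sorted(bad['diagnosis'].unique())} at rows {list(bad.index[:10])}"
        )
    if "prep" in df.columns:
        bad = df.loc[~df["prep"].isin(PREP_METHODS)]
        if len(bad):
            raise SchemaError(
                f"{path}: unknown prep methods {sorted(bad['prep'].unique())} "
                f"at rows {list(bad.index[:10])}"
            )
    age = pd.to_numeric(df["age"], errors="coerce")
    bad_rows = df.index[age.isna() & df["age"].notna()].tolist()
    if bad_rows:
        raise SchemaError(f"{path}: malformed age values at rows {bad_rows[:10]}")
    df["age"] = age
    if "hpv" in df.columns:
        hpv = df["hpv"].astype(str).str.strip().str.lower().map(_HPV_ALIASES)
        bad_rows = df.index[hpv.isna()].tolist()
        if bad_rows:
            raise SchemaError(f"{path}: unknown hpv values at rows {bad_rows[:10]}")
        df["hpv"] = hpv
    return df


def load_cells(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a cells table with its ``cmd_<class>`` columns."""
    df = _apply_mapping(pd.read_csv(path, comment="#"), column_map)
    missing = [c for c in CELL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cells table missing columns {missing}")
    cmd_cols = [c for c in df.columns if c.startswith("cmd_")]
    if not cmd_cols:
        raise SchemaError(f"{path}: cells table has no cmd_<class> columns")
    vals = df[cmd_cols].to_numpy(float)
    if not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
        bad = np.flatnonzero(
            ~np.all(np.isfinite(vals) & (vals >= 0) & (vals <= 1), axis=1)
        )
        raise SchemaError(
            f"{path}: CMD values outside [0, 1] at rows {bad[:10].tolist()}"
        )
    return df


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a CSV with an optional provenance header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
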