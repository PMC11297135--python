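"""Reading and writing the delimited hydrographic tables.

Comma-separated UTF-8 text with a header row in the canonical column
order (:data:`riacarb.world.COLUMNS`).  Missing optional labels (pH,
TA) are serialized as empty fields.  Floats are written with
``%.10g``, which round-trips the generator output to well below any
physically meaningful precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .world import COLUMNS, MANDATORY_NUMERIC

OPTIONAL_NUMERIC = ["ph", "ta_umol_kg"]
FLOAT_FORMAT = "%.10g"


class TableFormatError(ValueError):
    """Raised for malformed tables (missing columns, non-numeric cells)."""


def write_table(records: pd.DataFrame, path) -> None:
    """Write a table in the canonical column layout."""
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise TableFormatError(f"table is missing mandatory column(s): {missing}")
    records[COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    """Read a table, validating columns and cell types.

    Raises :class:`TableFormatError` naming the offending column, and
    for non-numeric cells the 1-based data line number.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "date": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise TableFormatError(f"unknown column(s): {unknown}")
    for col in MANDATORY_NUMERIC + OPTIONAL_NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableFormatError(
                f"non-numeric value in column {col!r} at data line {line}: "
                f"{df[col].iloc[line - 1]!r}"
            )
        if col in MANDATORY_NUMERIC and coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 1
            raise TableFormatError(f"missing value in mandatory column {col!r} at data line {line}")
        df[col] = coerced.astype(float)
    df["week"] = df["week"].astype(int)
    return df[COLUMNS]
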