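"""Reading and writing city tables as CSV.

The on-disk format is a plain CSV with a header and the documented column
order (:data:`hhrineq.schema.CITY_COLUMNS`).  Reading validates types and
value ranges so downstream code can assume a well-formed table; errors
carry the offending column and row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .exceptions import ParseError, SchemaError, ValidationError

__all__ = ["read_city_csv", "write_city_csv"]


def read_city_csv(path) -> pd.DataFrame:
    """Read and validate a city table.

    Raises
    ------
    SchemaError
        If required columns are missing (lists the names).
    ParseError
        If a numeric column contains an unparseable value (names the row).
    ValidationError
        If values violate the schema's range or level-set constraints.
    """
    path = Path(path)
    # round_trip parsing so write -> read reproduces floats bit-exactly
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.CITY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    extra = [c for c in raw.columns if c not in schema.CITY_COLUMNS]
    if extra:
        warnings.warn(
            f"{path.name}: ignoring extra column(s) {extra}", UserWarning, stacklevel=2
        )

    table = raw.loc[:, list(schema.CITY_COLUMNS)].copy()
    for col in schema.NUMERIC_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {table[col].iloc[row]!r} in "
                f"column {col!r} at row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"{path.name}: missing value in column {col!r} at row {row}")
        table[col] = numeric.astype(float)

    for col in schema.POSITIVE_COLUMNS:
        bad = table[col].to_numpy() <= 0.0
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path.name}: column {col!r} must be strictly positive; "
                f"value {table[col].iloc[row]} at row {row}"
            )
    for col in schema.PERCENT_COLUMNS:
        vals = table[col].to_numpy()
        bad = (vals < 0.0) | (vals > 100.0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path.name}: column {col!r} must lie in [0, 100]; "
                f"value {table[col].iloc[row]} at row {row}"
            )
    for col, levels in schema.CATEGORICAL_LEVELS.items():
        values = table[col].astype(str)
        unknown = sorted(set(values) - set(levels))
        if unknown:
            row = int(np.flatnonzero((~values.isin(levels)).to_numpy())[0])
            raise ValidationError(
                f"{path.name}: column {col!r} contains unknown level(s) "
                f"{unknown} (first at row {row})"
            )
        table[col] = values
    table["city_id"] = table["city_id"].astype(str)
    return table


def write_city_csv(table: pd.DataFrame, path) -> None:
    """Write a city table in the documented column order with a header."""
    missing = [c for c in schema.CITY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write table; missing column(s) {missing}")
    table.loc[:, list(schema.CITY_COLUMNS)].to_csv(path, index=False)
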