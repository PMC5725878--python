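"""Delimited-text I/O for applicant tables.

Dialect: UTF-8 CSV (configurable delimiter), mandatory header with columns
``x1``, ``x2``, ``y`` and optional ``z``, ``selected``. A missing outcome
is an empty field or ``NA``; tables are written with empty fields for
missing y. The ``selected`` flag, when absent, is inferred as y-present.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ApplicantTable, DataError

logger = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_table(path: str | Path, delimiter: str = ",") -> ApplicantTable:
    """Read an applicant table from a delimited text file.

    Raises :class:`DataError` if mandatory columns are absent, if a cell
    is non-numeric, or if a predictor value is missing (predictors must be
    measured in all applicants).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(
        path, sep=delimiter, na_values=_NA_VALUES, keep_default_na=False, dtype=str
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("x1", "x2", "y"):
        if col not in df.columns:
            raise DataError(f"missing mandatory column: {col!r} (found {list(df.columns)})")
    out = {}
    for col in ("x1", "x2", "y", "z"):
        if col not in df.columns:
            continue
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise DataError(
                f"non-numeric value in column {col!r} at row {int(bad[0]) if len(bad) else '?'}"
            ) from None
    parsed = pd.DataFrame(out)
    if "selected" in df.columns:
        parsed["selected"] = (
            df["selected"].str.strip().str.lower().map(
                {"true": True, "1": True, "false": False, "0": False}
            )
        )
        if parsed["selected"].isna().any():
            raise DataError("column 'selected' must contain true/false or 1/0")
    table = ApplicantTable(parsed)
    logger.info(
        "read %d rows from %s (%d incumbents, %d missing y)",
        table.n, path, table.n_selected, table.n_missing_y,
    )
    return table


def write_table(table: ApplicantTable, path: str | Path, delimiter: str = ",") -> None:
    """Write an applicant table; missing y becomes an empty field."""
    df = table.to_dataframe()
    df["selected"] = df["selected"].map({True: "true", False: "false"})
    df.to_csv(Path(path), sep=delimiter, index=False, na_rep="")
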