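"""CSV ingestion and validation.

Datasets travel as delimited text with a header row: the two outcome
columns (0/1) plus any number of covariate columns.  The delimiter is
auto-detected among comma, semicolon and tab.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import BivariateBinaryDataset

__all__ = ["read_dataset", "write_dataset", "sniff_delimiter"]

_DELIMITERS = (",", ";", "\t")


def sniff_delimiter(path) -> str:
    """Pick the delimiter (comma/semicolon/tab) most frequent in the header."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: file is empty")
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_dataset(
    path,
    outcome_cols: tuple[str, str] = ("y1", "y2"),
    covariate_cols: list[str] | None = None,
) -> BivariateBinaryDataset:
    """Read and validate a dataset from delimited text.

    Outcome columns are coerced to {0, 1}; any row with a missing value or
    a non-binary outcome is rejected with a row-numbered message (rows are
    1-based data rows, excluding the header).  Column order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    c1, c2 = outcome_cols
    for c in (c1, c2):
        if c not in df.columns:
            raise ValueError(f"{path}: outcome column {c!r} not found "
                             f"(columns: {list(df.columns)})")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (c1, c2)]
    missing_cols = [c for c in covariate_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: covariate columns not found: {missing_cols}")

    use = df[[c1, c2] + covariate_cols]
    na_rows = use.isna().any(axis=1)
    if na_rows.any():
        rows = (np.flatnonzero(na_rows) + 1).tolist()
        raise ValueError(f"{path}: missing values in data rows {rows}")
    for c in (c1, c2):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            r = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"{path}: non-binary outcome value {df[c].iloc[r - 1]!r} "
                f"in column {c!r}, data row {r}"
            )
    return BivariateBinaryDataset.from_frame(df, (c1, c2), covariate_cols)


def write_dataset(data: BivariateBinaryDataset, path) -> None:
    """Write a dataset as comma-delimited text (header: y1, y2, covariates)."""
    data.to_frame().to_csv(path, index=False)
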