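"""Delimited-text I/O for intensity matrices.

Dialect is fixed: comma separator, period decimal, UTF-8, header row, one
row per animal, a mandatory ``condition`` label column and an optional
``sex`` column; every other column is a numeric region/feature column.
Floats are written at 17 significant digits so a write/read round trip is
exact.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

LABEL_COLUMNS = ("condition", "sex")


def read_matrix(path) -> pd.DataFrame:
    """Read an intensity matrix, validating the dialect and shape."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names: {dupes}")
    if "condition" not in header:
        raise ValueError("missing required label column 'condition'")
    df = pd.read_csv(
        path,
        dtype={c: str for c in LABEL_COLUMNS if c in header},
        float_precision="round_trip",
    )
    if df.isna().any().any():
        raise ValueError("matrix contains missing cells or ragged rows")
    feature_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
    for c in feature_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            sample = str(df[c].iloc[0])
            if "," in sample:
                raise ValueError(
                    f"column {c!r} looks like comma-decimal numbers ({sample!r}); "
                    "the dialect requires period decimals"
                )
            raise ValueError(f"non-numeric cells in feature column {c!r}")
    df.index.name = "animal"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> Path:
    """Write a matrix in the fixed dialect; round-trips through read_matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    return path
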