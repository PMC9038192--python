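"""Delimited-text tables with lossless round-trips.

All outputs are tab-separated text with a header row; floats are
written with 17 significant digits so that read-after-write reproduces
them bit-for-bit (including NaN and infinities).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "write_matrix", "read_matrix"]


def write_table(records: pd.DataFrame, path) -> None:
    """Write a DataFrame as tab-separated text; exact float round-trip."""
    records.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NaN")


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    try:
        return pd.read_csv(
            path, sep="\t", na_values=["NaN"], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a 2-d array (e.g. a Fisher matrix) as delimited text."""
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.17g")


def read_matrix(path) -> np.ndarray:
    mat = np.loadtxt(Path(path), delimiter="\t")
    return np.atleast_2d(mat)
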