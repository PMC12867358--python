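"""Numeric cross-sectional tables with an explicit missing-cell notion.

The framework operates on rectangular numeric data (rows = observations,
columns = variables).  Missing cells are represented internally as NaN; on
disk the R-interoperable token ``NA`` is written and ``""``/``NA``/``NaN``
(case-insensitive) are accepted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = ["CellRef", "NumericTable", "read_table", "write_table", "missing_cells"]

#: tokens recognised as a missing cell on read (compared case-insensitively)
MISSING_TOKENS = {"", "na", "nan"}


class CellRef(NamedTuple):
    """0-based address of a table cell (reports print 1-based rows)."""

    row_index: int
    col_index: int


@dataclass
class NumericTable:
    """Rectangular numeric data with row/column labels and NaN missing marker.

    Invariants (enforced in ``validate``): at least 2 columns and 3 rows,
    every cell finite or NaN, no column entirely missing.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("table values must be a 2-D array")
        n_rows, n_cols = self.values.shape
        if not self.row_ids:
            self.row_ids = [str(i + 1) for i in range(n_rows)]
        if not self.col_ids:
            self.col_ids = [f"V{j + 1}" for j in range(n_cols)]
        self.validate()

    # -- shape ------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        n_rows, n_cols = self.values.shape
        if n_cols < 2:
            raise ValueError("table needs at least 2 columns")
        if n_rows < 3:
            raise ValueError("table needs at least 3 rows")
        if len(self.row_ids) != n_rows or len(self.col_ids) != n_cols:
            raise ValueError("row/column label lengths do not match data shape")
        if np.isinf(self.values).any():
            raise ValueError("table cells must be finite or missing")
        all_missing = np.isnan(self.values).all(axis=0)
        if all_missing.any():
            bad = [self.col_ids[j] for j in np.flatnonzero(all_missing)]
            raise ValueError(f"column(s) entirely missing: {', '.join(bad)}")

    def copy(self) -> "NumericTable":
        return NumericTable(self.values.copy(), list(self.row_ids), list(self.col_ids))

    def is_missing(self, cell: CellRef) -> bool:
        return bool(math.isnan(self.values[cell.row_index, cell.col_index]))

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def observed_column(self, j: int) -> np.ndarray:
        col = self.values[:, j]
        return col[~np.isnan(col)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def equals(self, other: "NumericTable") -> bool:
        if self.row_ids != other.row_ids or self.col_ids != other.col_ids:
            return False
        a, b = self.values, other.values
        return bool(np.array_equal(a, b, equal_nan=True))


def missing_cells(table: NumericTable) -> set[CellRef]:
    """Exactly the cells holding the missing marker."""
    rows, cols = np.nonzero(np.isnan(table.values))
    return {CellRef(int(r), int(c)) for r, c in zip(rows, cols)}


def _parse_cell(token: str, col_name: str) -> float:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(tok)
    except ValueError:
        raise ValueError(
            f"column {col_name!r} contains non-numeric value {token!r}"
        ) from None


def _sniff_delimiter(header_line: str) -> str:
    # bounded dialect surface: comma or semicolon, decimal point only
    return ";" if header_line.count(";") > header_line.count(",") else ","


def read_table(path, has_row_ids: bool = False) -> NumericTable:
    """Read a delimited text file (one header row) into a :class:`NumericTable`.

    Non-numeric cells other than the recognised missing tokens raise a
    ``ValueError`` naming the offending column.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip().strip('"') for h in lines[0].split(delim)]
    raw_rows = [ln.split(delim) for ln in lines[1:]]
    if has_row_ids:
        col_ids = header[1:]
        row_ids = [r[0].strip().strip('"') for r in raw_rows]
        raw_rows = [r[1:] for r in raw_rows]
    else:
        col_ids = header
        row_ids = [str(i + 1) for i in range(len(raw_rows))]
    if len(col_ids) < 2:
        raise ValueError(f"{path}: fewer than 2 data columns")
    values = np.empty((len(raw_rows), len(col_ids)), dtype=float)
    for i, row in enumerate(raw_rows):
        if len(row) != len(col_ids):
            raise ValueError(f"{path}: row {i + 1} has {len(row)} cells, expected {len(col_ids)}")
        for j, tok in enumerate(row):
            values[i, j] = _parse_cell(tok, col_ids[j])
    return NumericTable(values, row_ids, col_ids)


def write_table(table: NumericTable, path) -> None:
    """Write a table as CSV with ``NA`` missing tokens, round-trip faithful.

    Floats are serialised with 17 significant digits so that
    ``read_table(write_table(t))`` reproduces ``t`` cell for cell.
    """
    table.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(["id"] + list(table.col_ids)) + "\n")
        for i in range(table.n_rows):
            cells = [table.row_ids[i]]
            for j in range(table.n_cols):
                v = table.values[i, j]
                cells.append("NA" if math.isnan(v) else repr(float(v)))
            fh.write(",".join(cells) + "\n")


def long_results_to_frame(records: Iterable[tuple]) -> pd.DataFrame:
    """Long-format results carrier: one row per (method, variable, iteration, metric)."""
    df = pd.DataFrame(
        list(records),
        columns=["method", "variable", "iteration", "metric", "raw", "gated", "p_gate"],
    )
    if df.duplicated(["method", "variable", "iteration", "metric"]).any():
        raise ValueError("duplicate (method, variable, iteration, metric) keys")
    return df
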