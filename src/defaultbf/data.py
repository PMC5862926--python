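"""Typed rectangular data tables.

A :class:`DataTable` is a small wrapper around a pandas DataFrame that keeps a
measurement level (continuous / ordinal / nominal) for every column, the way a
statistics spreadsheet does.  Levels are guessed on load and may be overridden
per column.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataTable", "GroupDescriptives", "DataError",
    "read_csv", "write_csv", "descriptives", "wide_to_cells",
]

LEVELS = ("continuous", "ordinal", "nominal")

#: numeric columns with at most this many distinct values are guessed ordinal
ORDINAL_MAX_DISTINCT = 10

_MISSING = {"", "na", "nan", "n/a", "null", "none", "."}
_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


class DataError(ValueError):
    """Malformed input data or an invalid column request."""


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in _MISSING


def _try_float(cell: str) -> float | None:
    try:
        return float(cell)
    except ValueError:
        return None


class DataTable:
    """Ordered, typed columns of equal length with missing values allowed."""

    def __init__(self, columns: Mapping[str, Sequence] | pd.DataFrame,
                 levels: Mapping[str, str] | None = None):
        frame = pd.DataFrame(columns).copy()
        if frame.columns.duplicated().any():
            raise DataError("column names must be unique")
        self._frame = frame
        self._levels: dict[str, str] = {}
        levels = dict(levels or {})
        for name in frame.columns:
            level = levels.pop(name, None)
            if level is None:
                level = _guess_level(frame[name])
            self.set_level(name, level)
        if levels:
            raise DataError(f"levels given for unknown columns: {sorted(levels)}")

    # -- basic protocol ----------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self._frame)

    def level(self, name: str) -> str:
        self._check(name)
        return self._levels[name]

    def set_level(self, name: str, level: str) -> None:
        """Override the measurement level of a column, with validation."""
        self._check(name)
        if level not in LEVELS:
            raise DataError(f"unknown measurement level {level!r}")
        col = self._frame[name]
        if level in ("continuous", "ordinal"):
            numeric = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & numeric.isna()
            if bad.any():
                raise DataError(
                    f"column {name!r} cannot be {level}: non-numeric value "
                    f"{col[bad].iloc[0]!r}")
            self._frame[name] = numeric.astype(float)
        else:
            values = col[col.notna()]
            if values.nunique() < 1:
                raise DataError(f"nominal column {name!r} has no observed levels")
            self._frame[name] = col.astype(object)
        self._levels[name] = level

    def column(self, name: str) -> pd.Series:
        self._check(name)
        return self._frame[name]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def head(self, n: int) -> "DataTable":
        """The table restricted to its first ``n`` rows."""
        return DataTable(self._frame.iloc[:n].reset_index(drop=True),
                         dict(self._levels))

    def group_levels(self, name: str) -> list:
        """Distinct non-missing values in order of first appearance."""
        col = self.column(name)
        return list(pd.unique(col[col.notna()]))

    def _check(self, name: str) -> None:
        if name not in self._frame.columns:
            raise DataError(f"no such column: {name!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        return (self._levels == other._levels
                and self._frame.columns.tolist() == other._frame.columns.tolist()
                and self._frame.equals(other._frame))

    def __repr__(self) -> str:
        cols = ", ".join(f"{c} ({self._levels[c]})" for c in self.columns)
        return f"DataTable({self.n_rows} rows: {cols})"

    def to_dict(self) -> dict:
        """JSON-ready representation (missing values become None)."""
        frame = self._frame.astype(object).where(self._frame.notna(), None)
        return {"columns": [
            {"name": c, "level": self._levels[c], "values": frame[c].tolist()}
            for c in self.columns]}

    @classmethod
    def from_dict(cls, payload: dict) -> "DataTable":
        cols = {c["name"]: c["values"] for c in payload["columns"]}
        levels = {c["name"]: c["level"] for c in payload["columns"]}
        return cls(cols, levels)


def _guess_level(col: pd.Series) -> str:
    values = col[col.notna()]
    if len(values) == 0:
        return "nominal"
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any():
        return "nominal"
    return "continuous" if numeric.nunique() > ORDINAL_MAX_DISTINCT else "ordinal"


# -- CSV I/O ---------------------------------------------------------------

def read_csv(path: str | Path) -> DataTable:
    """Read a header-row CSV (UTF-8, comma separated, '.' decimal mark).

    Every column gets a best-guess measurement level: all-numeric with more
    than ORDINAL_MAX_DISTINCT distinct values -> continuous, all-numeric
    otherwise -> ordinal, anything else -> nominal.  Override afterwards with
    :meth:`DataTable.set_level`.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or all(len(r) == 0 for r in rows):
        raise DataError(f"{path}: empty file")
    header, *body = [r for r in rows if len(r) > 0]
    width = len(header)
    for i, row in enumerate(body, start=2):
        if len(row) != width:
            raise DataError(
                f"{path}: ragged row {i}: expected {width} fields, got {len(row)}")
    if len(set(header)) != width:
        raise DataError(f"{path}: duplicate column names in header")
    columns: dict[str, list] = {}
    for j, name in enumerate(header):
        cells = [row[j] for row in body]
        non_missing = [c for c in cells if not _is_missing(c)]
        if non_missing and all(_DECIMAL_COMMA.match(c.strip()) for c in non_missing):
            raise DataError(
                f"{path}: column {name!r} looks like a decimal-comma dialect "
                "(e.g. '1,5'); convert to '.' decimal marks first")
        if non_missing and all(_try_float(c) is not None for c in non_missing):
            columns[name] = [np.nan if _is_missing(c) else float(c) for c in cells]
        else:
            columns[name] = [None if _is_missing(c) else c for c in cells]
    return DataTable(columns)


def write_csv(table: DataTable, path: str | Path) -> None:
    """Write a DataTable; floats are kept to 15 significant digits."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(table.columns)
        frame = table.to_frame()
        for _, row in frame.iterrows():
            out = []
            for name in table.columns:
                v = row[name]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    out.append("")
                elif isinstance(v, float):
                    out.append(f"{v:.15g}")
                else:
                    out.append(str(v))
            writer.writerow(out)


# -- descriptives ----------------------------------------------------------

@dataclass(frozen=True)
class GroupDescriptives:
    """Per-group sample size, mean and standard deviation."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("group size must be at least 1")
        if self.sd < 0:
            raise DataError("standard deviation cannot be negative")

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n,
                "mean": self.mean, "sd": self.sd}


def descriptives(table: DataTable, dependent: str, group: str) -> list[GroupDescriptives]:
    """N, mean and sd of ``dependent`` per level of ``group``.

    Group rows appear in order of first appearance in the file; rows missing
    either variable are dropped pairwise.
    """
    if table.level(dependent) != "continuous":
        raise DataError(f"dependent column {dependent!r} must be continuous")
    if table.level(group) != "nominal":
        raise DataError(f"grouping column {group!r} must be nominal")
    y = table.column(dependent)
    g = table.column(group)
    keep = y.notna() & g.notna()
    out = []
    for level in table.group_levels(group):
        vals = y[keep & (g == level)].to_numpy(dtype=float)
        if vals.size == 0:
            raise DataError(f"group {level!r} has no non-missing observations")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(GroupDescriptives(str(level), int(vals.size),
                                     float(np.mean(vals)), sd))
    return out


# -- wide -> long reshaping for repeated measures ---------------------------

def wide_to_cells(table: DataTable,
                  factor_defs: Mapping[str, Sequence[str]],
                  cell_map: Mapping[str, Sequence[str]],
                  *, dependent: str = "value",
                  subject: str = "subject") -> DataTable:
    """Reshape one-column-per-cell data to long format with a subject column.

    ``factor_defs`` maps factor name -> ordered levels; ``cell_map`` maps a
    wide column name -> the cell it holds, as one level per factor in
    ``factor_defs`` order.  Every factorial cell must be covered exactly once.
    """
    import itertools

    factors = list(factor_defs)
    all_cells = {tuple(c) for c in itertools.product(*(factor_defs[f] for f in factors))}
    seen: dict[tuple, str] = {}
    for col, cell in cell_map.items():
        cell = tuple(cell)
        if cell not in all_cells:
            raise DataError(f"column {col!r} mapped to unknown cell {cell}")
        if cell in seen:
            raise DataError(f"cell {cell} mapped twice ({seen[cell]!r}, {col!r})")
        table._check(col)
        seen[cell] = col
    unmapped = sorted(all_cells - set(seen))
    if unmapped:
        raise DataError(f"unmapped cells: {unmapped}")

    n = table.n_rows
    subjects = [f"s{i + 1}" for i in range(n)]
    frames = []
    for cell in itertools.product(*(factor_defs[f] for f in factors)):
        col = seen[cell]
        chunk = {subject: subjects, dependent: table.column(col).to_numpy(dtype=float)}
        for f, lev in zip(factors, cell):
            chunk[f] = [lev] * n
        frames.append(pd.DataFrame(chunk))
    long = pd.concat(frames, ignore_index=True)
    levels = {subject: "nominal", dependent: "continuous",
              **{f: "nominal" for f in factors}}
    return DataTable(long[[subject, *factors, dependent]], levels)
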