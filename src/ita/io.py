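"""Reading and writing expression matrices and pipeline output tables.

Tabular dialects: plain TSV/CSV (first column gene ids, header row of time
labels) and a GEO series-matrix-style dialect where "!"-prefixed metadata
lines are skipped and the table sits between ``series_matrix_table_begin`` /
``series_matrix_table_end`` markers.  Time labels may carry "min" or "h"
suffixes; hours are converted to minutes on read.
"""

from __future__ import annotations

import io as _stdio
import re
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from ita.matrix import ExpressionMatrix

__all__ = [
    "parse_time_label",
    "read_expression",
    "write_expression",
    "write_metric_table",
    "read_metric_table",
]

_TIME_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(min|m|h|hr|hours?)?\s*$", re.IGNORECASE)


def parse_time_label(label: str) -> float:
    """Parse a time label to minutes ("20", "20min", "2h", "2 h" → 20/20/120/120)."""
    m = _TIME_RE.match(str(label))
    if m is None:
        raise ValueError(f"cannot parse time label {label!r}")
    value = float(m.group(1))
    unit = (m.group(2) or "min").lower()
    if unit.startswith("h"):
        value *= 60.0
    return value


def _frame_to_matrix(
    df: pd.DataFrame, condition_label: str, allow_zeros: bool
) -> ExpressionMatrix:
    gene_ids = [str(g) for g in df.iloc[:, 0]]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"duplicate gene id: {g!r}")
        seen.add(g)
    times = np.array([parse_time_label(c) for c in df.columns[1:]], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"time labels are not strictly increasing: {list(df.columns[1:])}")
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        parsed = pd.to_numeric(body[col], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy() & body[col].notna().to_numpy())[0]
        if parsed.isna().any():
            i = int(np.nonzero(parsed.isna().to_numpy())[0][0]) if bad.size == 0 else int(bad[0])
            raise ValueError(
                f"non-numeric cell at row {i} (gene {gene_ids[i]!r}), column {col!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        time_points_min=times,
        values=values,
        condition_label=condition_label,
        allow_zeros=allow_zeros,
    )


def read_expression(
    path: Union[str, Path],
    dialect: str = "tsv",
    condition_label: str | None = None,
    allow_zeros: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from a tabular file.

    Parameters
    ----------
    path
        Input file; header row of time labels, first column gene ids.
    dialect
        ``"tsv"``, ``"csv"``, or ``"series_matrix"``.
    allow_zeros
        Accept zero entries (to be fixed by :func:`ita.variability.handle_zeros`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    label = condition_label if condition_label is not None else path.stem
    if dialect in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",", dtype=str)
    elif dialect == "series_matrix":
        lines = path.read_text().splitlines()
        in_table = False
        table_lines: list[str] = []
        for line in lines:
            stripped = line.strip()
            if "series_matrix_table_begin" in stripped.lower():
                in_table = True
                continue
            if "series_matrix_table_end" in stripped.lower():
                in_table = False
                continue
            if stripped.startswith("!") or not stripped:
                continue
            if in_table:
                table_lines.append(line)
        if not table_lines:
            raise ValueError(f"no series-matrix table found in {path}")
        df = pd.read_csv(_stdio.StringIO("\n".join(table_lines)), sep="\t", dtype=str)
        df.columns = [str(c).strip().strip('"') for c in df.columns]
        df.iloc[:, 0] = df.iloc[:, 0].str.strip('"')
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(df, label, allow_zeros)


def write_expression(m: ExpressionMatrix, path: Union[str, Path]) -> None:
    """Write a matrix as TSV (gene_id + minute-labelled columns, 12 sig. digits)."""
    df = pd.DataFrame(m.values, columns=[f"{t:g}" for t in m.time_points_min])
    df.insert(0, "gene_id", list(m.gene_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_metric_table(table, path: Union[str, Path]) -> None:
    """Write a metric table (EntropyTable / MITable / EntropyMap or DataFrame) as TSV.

    Values round-trip at 12 significant digits; an empty table yields a
    header-only file.
    """
    df = table if isinstance(table, pd.DataFrame) else table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metric_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
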