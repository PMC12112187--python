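"""Core containers: the expression matrix and center-of-mass (CM) series.

An :class:`ExpressionMatrix` holds raw positive expression values for N genes
at T time points (minutes), together with their natural-log view.  Gene-set
centers of mass — per-time-point means of log expression, each gene treated as
unit mass — are the coherent collective coordinates the whole analysis is
built on: the CM of the whole expression system (WES) is the genome attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ExpressionMatrix", "CMSeries", "center_of_mass", "centered_view"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × time-points expression grid on the raw (positive) scale.

    Parameters
    ----------
    gene_ids
        Unique gene/probe identifiers, one per row.
    time_points_min
        Strictly increasing time points in minutes, length T ≥ 3.
    values
        (N, T) grid of finite raw expression values.  Must be strictly
        positive unless ``allow_zeros`` is set (pre zero-handling state);
        the log view is only available once all values are positive.
    condition_label
        Free-text condition tag (e.g. ``"EGF"``, ``"HRG"``, ``"synthetic"``).
    """

    gene_ids: tuple[str, ...]
    time_points_min: np.ndarray
    values: np.ndarray
    condition_label: str = ""
    allow_zeros: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        gene_ids = tuple(str(g) for g in self.gene_ids)
        tp = np.asarray(self.time_points_min, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {vals.shape}")
        n, t = vals.shape
        if len(gene_ids) != n:
            raise ValueError(f"{len(gene_ids)} gene ids for {n} rows")
        if tp.ndim != 1 or tp.size != t:
            raise ValueError(f"{tp.size} time points for {t} columns")
        if tp.size < 3:
            raise ValueError(f"need at least 3 time points, got {tp.size}")
        if np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be non-negative and strictly increasing")
        seen: set[str] = set()
        for g in gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id: {g!r}")
            seen.add(g)
        if not np.all(np.isfinite(vals)):
            raise ValueError("values contain NaN or Inf")
        if self.allow_zeros:
            if np.any(vals < 0):
                raise ValueError("values must be non-negative")
        elif np.any(vals <= 0):
            raise ValueError("values must be strictly positive (handle zeros first)")
        tp.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "time_points_min", tp)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.time_points_min.size

    @property
    def log_values(self) -> np.ndarray:
        """Natural log of the raw values (requires strictly positive values)."""
        cached = self.__dict__.get("_log_values")
        if cached is None:
            if np.any(self.values <= 0):
                raise ValueError("log view undefined: matrix contains zeros")
            cached = np.log(self.values)
            cached.setflags(write=False)
            object.__setattr__(self, "_log_values", cached)
        return cached

    def gene_index(self, gene_set: Iterable[str]) -> np.ndarray:
        """Row indices for a set of gene ids (error on unknown ids)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = np.array([lookup[g] for g in gene_set], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown gene id: {e.args[0]!r}") from None
        return idx


@dataclass(frozen=True)
class CMSeries:
    """Center of mass of log expression over a gene set, one value per time point."""

    cm: np.ndarray
    gene_set_label: str = "WES"

    def __post_init__(self) -> None:
        cm = np.asarray(self.cm, dtype=float)
        if cm.ndim != 1:
            raise ValueError("cm must be a 1-D series")
        if not np.all(np.isfinite(cm)):
            raise ValueError("cm contains NaN or Inf")
        cm.setflags(write=False)
        object.__setattr__(self, "cm", cm)


def center_of_mass(
    m: ExpressionMatrix,
    gene_set: Sequence[str] | None = None,
    label: str | None = None,
) -> CMSeries:
    """Per-time-point mean of log expression over a gene set (unit masses).

    ``gene_set=None`` means the whole expression system (WES).
    """
    if gene_set is None:
        idx = np.arange(m.n_genes)
        label = label or "WES"
    else:
        gene_set = list(gene_set)
        if not gene_set:
            raise ValueError("gene_set is empty")
        idx = m.gene_index(gene_set)
        label = label or f"set-{len(gene_set)}"
    return CMSeries(cm=m.log_values[idx].mean(axis=0), gene_set_label=label)


def centered_view(m: ExpressionMatrix, cm: CMSeries | None = None) -> np.ndarray:
    """Log expression after subtracting the time-dependent WES center of mass.

    Column means over the WES are zero by construction; adding a constant to
    every log value leaves the view unchanged.
    """
    if cm is None:
        cm = center_of_mass(m)
    if cm.cm.size != m.n_times:
        raise ValueError(
            f"CM length {cm.cm.size} does not match {m.n_times} time points"
        )
    return m.log_values - cm.cm[np.newaxis, :]
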