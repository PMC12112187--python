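"""Critical-point (CP) region detection and the CP/PES partition.

Genes ranked by ln(nrmsf) are grouped, and for each consecutive time pair the
ratio of group-ensemble-average log expression,

    r = <ln eps(t_{j+1})> / <ln eps(t_j)>,

is traced along the ln(nrmsf) axis.  Most groups stay near r = 1 (coherent
stochastic behavior of large ensembles); the CP region stands out as a narrow
ln(nrmsf) window with *bimodal singular* behavior — excursions both above and
below 1.  The detected peak interval is standardized to the 0.1 grid with a
minimum width of 0.2, and the whole expression system (WES) is split into the
CP gene set (open interval membership) and the peripheral expression system
(PES, the remainder).

Ratios are taken on non-centered log expression: group means of CM-centered
values hover around zero and their ratios would be ill-defined; CM centering
enters only at the entropy-estimation stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ita.matrix import ExpressionMatrix
from ita.variability import GroupTable, VariabilityTable

__all__ = [
    "RatioCurves",
    "CPPartition",
    "ratio_curves",
    "detect_cp_peaks",
    "standardize_cp_interval",
    "partition",
]


@dataclass(frozen=True)
class RatioCurves:
    """Group-ratio curves: one curve per consecutive time pair.

    ``ratios[g, j]`` is the ratio of group g's mean log expression between
    t_{j+1} and t_j; ``x`` holds each group's ensemble-average coordinate
    ln(<nrmsf>).  Only non-excluded groups are present.
    """

    x: np.ndarray  # (G,) group coordinates on the ln(nrmsf) axis
    ratios: np.ndarray  # (G, T-1)
    group_indices: np.ndarray  # indices into the originating GroupTable
    time_pairs: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class CPPartition:
    """Standardized CP interval and the induced CP/PES gene sets."""

    peak_interval: tuple[float, float]
    cp_interval: tuple[float, float]
    cp_gene_ids: tuple[str, ...]
    pes_gene_ids: tuple[str, ...]

    @property
    def n_cp(self) -> int:
        return len(self.cp_gene_ids)

    @property
    def n_pes(self) -> int:
        return len(self.pes_gene_ids)


def ratio_curves(m: ExpressionMatrix, g: GroupTable) -> RatioCurves:
    """Between-time-point ratios of group-mean log expression.

    Excluded groups are omitted.  A group-mean log expression of exactly 0
    makes the ratio undefined; it is emitted as NaN with a warning.
    """
    keep = np.flatnonzero(~g.excluded)
    if keep.size == 0:
        raise ValueError("all groups are excluded; lower min_group or increase N")
    logx = m.log_values
    means = np.stack([logx[g.groups[i]].mean(axis=0) for i in keep])  # (G, T)
    denom = means[:, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(denom != 0.0, means[:, 1:] / denom, np.nan)
    if np.isnan(ratios).any():
        warnings.warn(
            "group-mean log expression of 0 encountered; ratio emitted as missing",
            stacklevel=2,
        )
    tp = m.time_points_min
    pairs = tuple((float(tp[j]), float(tp[j + 1])) for j in range(tp.size - 1))
    return RatioCurves(
        x=g.ln_mean_nrmsf[keep],
        ratios=ratios,
        group_indices=keep,
        time_pairs=pairs,
    )


def detect_cp_peaks(
    rc: RatioCurves,
    deviation_quantile: float = 0.98,
    bimodal_frac: float = 0.25,
) -> tuple[float, float] | None:
    """Locate the bimodal-singular peak interval on the ln(nrmsf) axis.

    Each group's deviation score is max_j |r - 1| over time pairs.  Candidate
    groups must (a) score at or above the ``deviation_quantile`` of all group
    scores, and (b) be bimodal: their own curve must swing both above and
    below 1, each excursion at least ``bimodal_frac`` of the group's score —
    a pulse response produces an entry ratio > 1 and an exit ratio < 1 (or
    vice versa), whereas a one-sided drift does not.

    Returns the [min, max] of candidate group coordinates, or ``None`` when
    no group qualifies ("no CP detected", distinct from an error).
    """
    if rc.ratios.shape[0] < 3:
        raise ValueError("need at least 3 groups to detect a CP")
    dev = rc.ratios - 1.0
    scores = np.nanmax(np.abs(dev), axis=1)
    up = np.nanmax(dev, axis=1)
    down = -np.nanmin(dev, axis=1)
    threshold = np.nanquantile(scores, deviation_quantile)
    candidates = (
        (scores >= threshold)
        & (scores > 0)
        & (up >= bimodal_frac * scores)
        & (down >= bimodal_frac * scores)
        & (up > 0)
        & (down > 0)
    )
    if not candidates.any():
        return None
    xc = rc.x[candidates]
    return (float(xc.min()), float(xc.max()))


def standardize_cp_interval(
    peak_interval: tuple[float, float],
    grid: float = 0.1,
    min_width: float = 0.2,
) -> tuple[float, float]:
    """Round the peak interval outward to the 0.1 grid, enforcing width 0.2.

    The lower endpoint is floored and the upper is ceiled to multiples of
    ``grid``.  If the result is narrower than ``min_width`` it is widened in
    grid steps, lower edge first, until the width is reached — e.g. a
    degenerate (-2.5, -2.5) becomes (-2.6, -2.4).
    """
    lo, hi = peak_interval
    if lo > hi:
        raise ValueError("peak interval must have lo <= hi")
    inv = 1.0 / grid
    # tiny nudges guard against binary representation jitter at grid points
    lo_s = math.floor(lo * inv + 1e-9) / inv
    hi_s = math.ceil(hi * inv - 1e-9) / inv
    widen_lo = True
    while hi_s - lo_s < min_width - 1e-12:
        if widen_lo:
            lo_s = round((lo_s - grid) * inv) / inv
        else:
            hi_s = round((hi_s + grid) * inv) / inv
        widen_lo = not widen_lo
    return (round(lo_s * inv) / inv, round(hi_s * inv) / inv)


def partition(
    v: VariabilityTable,
    cp_interval: tuple[float, float],
    peak_interval: tuple[float, float] | None = None,
) -> CPPartition:
    """Split genes with defined ln(nrmsf) into CP and PES.

    Membership is by the open interval lo < ln(nrmsf) < hi; genes exactly at
    an endpoint belong to the PES.  An interval selecting no genes is an
    error; an empty PES is returned with a warning (downstream joint
    estimation will fail on it).
    """
    lo, hi = cp_interval
    if lo > hi:
        raise ValueError("cp_interval must have lo <= hi")
    defined = v.defined
    in_cp = defined & (v.ln_nrmsf > lo) & (v.ln_nrmsf < hi)
    in_pes = defined & ~in_cp
    if not in_cp.any():
        raise ValueError(f"interval ({lo}, {hi}) selects no genes")
    if not in_pes.any():
        warnings.warn("PES is empty: CP interval covers every gene", stacklevel=2)
    ids = np.asarray(v.gene_ids, dtype=object)
    return CPPartition(
        peak_interval=peak_interval if peak_interval is not None else cp_interval,
        cp_interval=cp_interval,
        cp_gene_ids=tuple(ids[in_cp]),
        pes_gene_ids=tuple(ids[in_pes]),
    )
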