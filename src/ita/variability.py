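"""Temporal-variability ranking of genes: rmsf, nrmsf and ln(nrmsf).

The root-mean-square fluctuation of gene *i*,

    rmsf_i = sqrt( (1/T) * sum_j ( eps_i(t_j) - <eps_i> )^2 ),

is the population standard deviation (divide by T, not T−1) of its expression
trajectory; by default "expression" is the natural-log view.  Normalizing by
the dataset maximum gives nrmsf in (0, 1], whose natural log is the
time-independent axis along which genes are sorted and grouped.  The per-gene
variability acts as a proxy for chromatin flexibility: high-variability genes
sit in accessible, dynamically remodelled chromatin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ita.matrix import ExpressionMatrix

__all__ = [
    "VariabilityTable",
    "GroupTable",
    "compute_rmsf",
    "handle_zeros",
    "group_by_variability",
]


@dataclass(frozen=True)
class VariabilityTable:
    """Per-gene rmsf, nrmsf = rmsf/max(rmsf), and ln(nrmsf).

    Genes with zero rmsf (constant trajectories) have undefined ln(nrmsf)
    (NaN) and are excluded from ranking.  ``sort_order`` lists gene indices
    with defined ln(nrmsf) in descending ln(nrmsf) order.
    """

    gene_ids: tuple[str, ...]
    rmsf: np.ndarray
    nrmsf: np.ndarray
    ln_nrmsf: np.ndarray
    sort_order: np.ndarray
    scale: str = "log"

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of genes with defined ln(nrmsf)."""
        return np.isfinite(self.ln_nrmsf)


@dataclass(frozen=True)
class GroupTable:
    """Contiguous ln(nrmsf) grouping of the ranked genes.

    ``groups[g]`` are gene indices (into the VariabilityTable) of group g,
    ordered from high to low ln(nrmsf).  ``mean_ln_nrmsf`` is the per-group
    mean of ln(nrmsf); ``ln_mean_nrmsf`` is ln of the group-mean nrmsf — the
    ensemble-average dot used as the x-coordinate of group-ratio curves.
    """

    groups: tuple[np.ndarray, ...]
    mean_ln_nrmsf: np.ndarray
    ln_mean_nrmsf: np.ndarray
    sizes: np.ndarray
    excluded: np.ndarray
    k: int
    mode: str
    min_group: int


def compute_rmsf(m: ExpressionMatrix, scale: str = "log") -> VariabilityTable:
    """Compute the variability table of a matrix.

    Parameters
    ----------
    m
        Expression matrix (strictly positive for the log scale).
    scale
        ``"log"`` (default) computes rmsf on natural-log expression;
        ``"raw"`` on the raw scale (sensitivity analysis only).
    """
    if scale == "log":
        x = m.log_values
    elif scale == "raw":
        x = m.values
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if m.n_times < 2:
        raise ValueError("need at least 2 time points for rmsf")
    rmsf = x.std(axis=1, ddof=0)  # population SD: divide by T
    max_rmsf = rmsf.max()
    if max_rmsf == 0.0:
        raise ValueError("degenerate variability: all genes constant in time")
    nrmsf = rmsf / max_rmsf
    with np.errstate(divide="ignore"):
        ln_nrmsf = np.where(nrmsf > 0, np.log(np.maximum(nrmsf, 1e-300)), np.nan)
    n_constant = int(np.sum(rmsf == 0))
    if n_constant:
        warnings.warn(
            f"{n_constant} constant gene(s) have undefined ln(nrmsf) and are "
            "excluded from ranking",
            stacklevel=2,
        )
    defined = np.isfinite(ln_nrmsf)
    order = np.flatnonzero(defined)[np.argsort(-ln_nrmsf[defined], kind="stable")]
    return VariabilityTable(
        gene_ids=m.gene_ids,
        rmsf=rmsf,
        nrmsf=nrmsf,
        ln_nrmsf=ln_nrmsf,
        sort_order=order,
        scale=scale,
    )


def handle_zeros(
    m: ExpressionMatrix,
    noise_scale: float = 1e-2,
    n_ensemble: int = 100,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replace zero entries by an ensemble average of small uniform noise.

    Each zero becomes the mean of ``n_ensemble`` draws from
    Uniform(0, noise_scale) — expectation noise_scale/2 — so the log transform
    is defined while coherent stochastic behavior is preserved.  Nonzero
    entries are untouched; a matrix without zeros is returned unchanged.
    """
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    if n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    vals = m.values
    if np.any(vals < 0):
        raise ValueError("negative expression values")
    zeros = vals == 0
    if not zeros.any():
        return m
    rng = np.random.default_rng(seed)
    n_zero = int(zeros.sum())
    repl = rng.uniform(0.0, noise_scale, size=(n_ensemble, n_zero)).mean(axis=0)
    out = vals.copy()
    out[zeros] = repl
    return ExpressionMatrix(
        gene_ids=m.gene_ids,
        time_points_min=m.time_points_min,
        values=out,
        condition_label=m.condition_label,
    )


def group_by_variability(
    v: VariabilityTable,
    k: int = 40,
    mode: str = "equal_count",
    min_group: int = 200,
) -> GroupTable:
    """Split the ranked genes into k groups along ln(nrmsf).

    ``equal_count`` (default) splits the descending ln(nrmsf) order into k
    contiguous blocks whose sizes differ by at most one; ``equal_width``
    splits the ln(nrmsf) range into k equal intervals.  Groups smaller than
    ``min_group`` are flagged excluded (insufficient convergence of the group
    CM at the spectrum extremes) but retained in the table.
    """
    order = v.sort_order
    n = order.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genes with defined ln(nrmsf)")
    if mode == "equal_count":
        groups = [np.asarray(g) for g in np.array_split(order, k)]
    elif mode == "equal_width":
        ln = v.ln_nrmsf[order]
        lo, hi = ln.min(), ln.max()
        edges = np.linspace(lo, hi, k + 1)
        # descending order: bin by distance from the top edge
        bins = np.clip(np.searchsorted(edges, ln, side="left") - 1, 0, k - 1)
        groups = [order[bins == (k - 1 - g)] for g in range(k)]
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    sizes = np.array([g.size for g in groups])
    mean_ln = np.array(
        [v.ln_nrmsf[g].mean() if g.size else np.nan for g in groups]
    )
    ln_mean = np.array(
        [np.log(v.nrmsf[g].mean()) if g.size else np.nan for g in groups]
    )
    excluded = sizes < min_group
    return GroupTable(
        groups=tuple(groups),
        mean_ln_nrmsf=mean_ln,
        ln_mean_nrmsf=ln_mean,
        sizes=sizes,
        excluded=excluded,
        k=k,
        mode=mode,
        min_group=min_group,
    )
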