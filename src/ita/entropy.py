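"""Plug-in histogram entropy and joint-histogram mutual information (nats).

These are deliberately the plain maximum-likelihood ("plug-in") estimators:
S = -sum p ln p over occupied histogram bins, with probabilities taken as
relative counts.  No bias correction is applied by default — the pipeline's
robustness comes from fixing sample size and bin count and averaging over
bootstrap iterations, so entropy behaves as a state function whose bin-count
offset is constant across time points.  Values outside the bin range are
clamped to the end bins.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "histogram_entropy",
    "joint_histogram_entropy",
    "bin_indices",
    "entropy_from_counts",
]


def entropy_from_counts(counts: np.ndarray) -> float:
    """-sum p ln p of a count table; empty bins contribute 0."""
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty count table")
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Equal-width bin index of each value, clamping outliers to end bins."""
    edges = np.asarray(edges, dtype=float)
    nbins = edges.size - 1
    if nbins < 1:
        raise ValueError("need at least one bin")
    lo, hi = edges[0], edges[-1]
    width = (hi - lo) / nbins
    if width <= 0:  # degenerate range: everything in one bin
        return np.zeros(np.shape(values), dtype=np.int64)
    idx = np.floor((np.asarray(values, dtype=float) - lo) / width).astype(np.int64)
    return np.clip(idx, 0, nbins - 1)


def histogram_entropy(sample, edges) -> float:
    """Shannon entropy (nats) of a sample under an equal-width histogram.

    Parameters
    ----------
    sample
        One or more real values.
    edges
        Bin edges; values outside are clamped to the end bins.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size == 0:
        raise ValueError("empty sample")
    edges = np.asarray(edges, dtype=float)
    counts = np.bincount(bin_indices(sample, edges), minlength=edges.size - 1)
    return entropy_from_counts(counts)


def joint_histogram_entropy(
    x, y, edges_x, edges_y
) -> tuple[float, float, float, float]:
    """Joint entropy and mutual information of paired samples.

    The 2-D count table is built once; marginal entropies are computed from
    the *same* table, which makes I = S_x + S_y - S_joint non-negative
    exactly (up to float rounding, clipped at 0).

    Returns
    -------
    (S_joint, S_marg_x, S_marg_y, I) in nats.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length non-empty samples")
    bx = bin_indices(x, np.asarray(edges_x, dtype=float))
    by = bin_indices(y, np.asarray(edges_y, dtype=float))
    nbx = len(edges_x) - 1
    nby = len(edges_y) - 1
    table = np.bincount(bx * nby + by, minlength=nbx * nby).reshape(nbx, nby)
    s_joint = entropy_from_counts(table)
    s_x = entropy_from_counts(table.sum(axis=1))
    s_y = entropy_from_counts(table.sum(axis=0))
    mi = s_x + s_y - s_joint
    if mi < -1e-9:  # mathematically impossible with shared-table marginals
        raise AssertionError(f"negative mutual information {mi}")
    return s_joint, s_x, s_y, max(mi, 0.0)
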