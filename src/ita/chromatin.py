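"""Entropy decomposition along the ln(nrmsf) axis: chromatin-state maps.

Each ln(nrmsf) bin is read as a coarse chromatin state; the per-gene entropy
contribution of a bootstrap sample is credited to the sampled gene's
ln(nrmsf) bin, yielding a per-time-point profile whose bins sum exactly to
the plug-in entropy of the whole expression system.  Consecutive-time
differences of the profile (the ΔS map) expose folding (ΔS < 0) and
unfolding (ΔS > 0) dynamics, intermittent CP-like bimodal patterns inside
the CP window, and the fold/unfold transition point where the ΔS profile
changes sign.

The per-gene contribution is (−p_b ln p_b) / n_b, where b is the gene's
expression bin in that iteration and n_b the sampled occupancy of b.  The
literal per-gene term −p ln p (each of the n_b co-binned genes carrying the
whole bin term) over-counts shared bins and cannot sum to the entropy; the
occupancy-normalized form is the unique per-sample assignment that preserves
the total, and is the default.  The literal variant is available behind
``literal_contributions=True`` for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from ita.bootstrap import BootstrapConfig
from ita.entropy import bin_indices
from ita.matrix import ExpressionMatrix, centered_view
from ita.variability import VariabilityTable

__all__ = [
    "EntropyMap",
    "DeltaEntropyMap",
    "entropy_decomposition",
    "delta_map",
    "flag_cp_bimodal",
    "transition_point",
]


@dataclass(frozen=True)
class EntropyMap:
    """ln(nrmsf)-bin × time-point matrix of entropy contributions.

    ``contributions[b, j]`` is the (bootstrap-averaged) entropy credited to
    ln(nrmsf) bin b at time t_j; columns sum to ``s_wes`` — the matching
    whole-system entropy — exactly.
    """

    nrmsf_edges: np.ndarray  # (B+1,) ln(nrmsf) bin edges
    time_points_min: np.ndarray  # (T,)
    contributions: np.ndarray  # (B, T)
    s_wes: np.ndarray  # (T,)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.nrmsf_edges[:-1] + self.nrmsf_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        b, t = np.meshgrid(
            np.arange(self.contributions.shape[0]),
            np.arange(self.contributions.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "ln_nrmsf_bin": b.ravel(),
                "bin_center": self.bin_centers[b.ravel()],
                "time_min": self.time_points_min[t.ravel()],
                "contribution": self.contributions.ravel(),
            }
        )


@dataclass(frozen=True)
class DeltaEntropyMap:
    """Per-bin entropy changes over consecutive time intervals ((B, T-1))."""

    nrmsf_edges: np.ndarray
    interval_starts_min: np.ndarray
    interval_ends_min: np.ndarray
    values: np.ndarray  # (B, T-1)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.nrmsf_edges[:-1] + self.nrmsf_edges[1:])

    def sign_labels(self) -> np.ndarray:
        """"unfolding" where ΔS > 0, "folding" where ΔS < 0, "" at 0."""
        out = np.full(self.values.shape, "", dtype=object)
        out[self.values > 0] = "unfolding"
        out[self.values < 0] = "folding"
        return out

    def to_frame(self) -> pd.DataFrame:
        b, t = np.meshgrid(
            np.arange(self.values.shape[0]),
            np.arange(self.values.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "ln_nrmsf_bin": b.ravel(),
                "bin_center": self.bin_centers[b.ravel()],
                "interval_start_min": self.interval_starts_min[t.ravel()],
                "interval_end_min": self.interval_ends_min[t.ravel()],
                "delta_s": self.values.ravel(),
            }
        )


def entropy_decomposition(
    m: ExpressionMatrix,
    v: VariabilityTable,
    cfg: BootstrapConfig = BootstrapConfig(),
    n_nrmsf_bins: int = 80,
    full_population: bool = False,
    literal_contributions: bool = False,
) -> EntropyMap:
    """Decompose the WES entropy over ln(nrmsf) bins at every time point.

    Bootstrap mode (default) samples ``cfg.sample_size`` genes with
    replacement per iteration and averages the per-bin credited
    contributions over ``cfg.iters_entropy[1]`` iterations and
    ``cfg.n_runs`` runs; ``full_population=True`` instead uses every gene
    once (exact plug-in decomposition, no sampling).  Empty ln(nrmsf) bins
    contribute 0.
    """
    if len(v.gene_ids) != m.n_genes:
        raise ValueError("variability table does not match the matrix")
    defined = np.flatnonzero(v.defined)
    ln = v.ln_nrmsf[defined]
    nrmsf_edges = np.linspace(ln.min(), ln.max(), n_nrmsf_bins + 1)
    gene_bin = bin_indices(ln, nrmsf_edges)

    values = (centered_view(m) if cfg.centered else m.log_values)[defined]
    lo, hi = float(values.min()), float(values.max())
    expr_edges = np.linspace(lo, hi, cfg.n_bins + 1)
    binned = bin_indices(values, expr_edges)  # (Nd, T)

    T = m.n_times
    nb = cfg.n_bins
    contributions = np.zeros((n_nrmsf_bins, T))

    if full_population:
        n = defined.size
        for j in range(T):
            counts = np.bincount(binned[:, j], minlength=nb)
            p = counts / n
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            if literal_contributions:
                w = term[binned[:, j]]
            else:
                w = term[binned[:, j]] / np.maximum(counts[binned[:, j]], 1)
            contributions[:, j] = np.bincount(gene_bin, weights=w, minlength=n_nrmsf_bins)
        s_wes = contributions.sum(axis=0)
        if literal_contributions:
            # literal mode does not conserve the total; recompute S directly
            s_wes = np.array(
                [-_plogp_sum(np.bincount(binned[:, j], minlength=nb) / defined.size)
                 for j in range(T)]
            )
        return EntropyMap(nrmsf_edges, m.time_points_min, contributions, s_wes)

    iters = cfg.iters_entropy[1]
    root = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    n = defined.size
    acc = np.zeros((n_nrmsf_bins, T))
    for r in range(cfg.n_runs):
        for j, t_ss in enumerate(root[r].spawn(T)):
            rng = np.random.default_rng(t_ss)
            draws = rng.integers(0, n, size=(iters, cfg.sample_size))
            b = binned[:, j][draws]  # (iters, sample)
            off = (np.arange(iters) * nb)[:, None]
            counts = np.bincount((b + off).ravel(), minlength=iters * nb)
            counts = counts.reshape(iters, nb)
            p = counts / cfg.sample_size
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            gathered = np.take_along_axis(term, b, axis=1)
            if not literal_contributions:
                occ = np.take_along_axis(counts, b, axis=1)
                gathered = gathered / np.maximum(occ, 1)
            nb_ids = gene_bin[draws] + (np.arange(iters) * n_nrmsf_bins)[:, None]
            col = np.bincount(
                nb_ids.ravel(), weights=gathered.ravel(),
                minlength=iters * n_nrmsf_bins,
            ).reshape(iters, n_nrmsf_bins)
            acc[:, j] += col.mean(axis=0)
    contributions = acc / cfg.n_runs
    s_wes = contributions.sum(axis=0)
    return EntropyMap(nrmsf_edges, m.time_points_min, contributions, s_wes)


def _plogp_sum(p: np.ndarray) -> float:
    q = p[p > 0]
    return float((q * np.log(q)).sum())


def delta_map(em: EntropyMap) -> DeltaEntropyMap:
    """ΔS(bin, j) = contribution(bin, t_{j+1}) − contribution(bin, t_j).

    Columns telescope: summing a ΔS column over bins gives
    S(WES, t_{j+1}) − S(WES, t_j).
    """
    if em.time_points_min.size < 2:
        raise ValueError("need at least 2 time points")
    return DeltaEntropyMap(
        nrmsf_edges=em.nrmsf_edges,
        interval_starts_min=em.time_points_min[:-1],
        interval_ends_min=em.time_points_min[1:],
        values=np.diff(em.contributions, axis=1),
    )


def flag_cp_bimodal(
    dm: DeltaEntropyMap,
    cp_window: tuple[float, float],
    threshold_sd: float = 2.0,
) -> np.ndarray:
    """Flag intervals whose CP window shows a bimodal ΔS excursion.

    An interval is flagged when, inside the CP ln(nrmsf) window, the ΔS
    profile has both a positive and a negative excursion, each exceeding
    ``threshold_sd`` robust standard deviations (1.4826 × MAD) of that
    interval's ΔS over all bins.
    """
    lo, hi = cp_window
    centers = dm.bin_centers
    in_win = (centers > lo) & (centers < hi)
    if not in_win.any():
        raise ValueError("cp_window narrower than one ln(nrmsf) bin")
    flags = np.zeros(dm.values.shape[1], dtype=bool)
    for j in range(dm.values.shape[1]):
        col = dm.values[:, j]
        sd = 1.4826 * np.median(np.abs(col - np.median(col)))
        if sd == 0:
            continue
        win = col[in_win]
        flags[j] = bool((win > threshold_sd * sd).any() and (win < -threshold_sd * sd).any())
    return flags


def transition_point(
    profile, centers
) -> tuple[float | None, list[float]]:
    """Locate the fold/unfold sign change of a ΔS-vs-ln(nrmsf) profile.

    Scans consecutive bin pairs with opposite ΔS signs and linearly
    interpolates each zero crossing.  Returns the crossing nearest the
    largest-magnitude pair (the principal transition point) plus the list of
    all crossings; (None, []) with no sign change.
    """
    y = np.asarray(profile, dtype=float)
    x = np.asarray(centers, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValueError("profile and centers must align with length >= 2")
    crossings: list[float] = []
    weights: list[float] = []
    for i in range(y.size - 1):
        if y[i] * y[i + 1] < 0:
            t = y[i] / (y[i] - y[i + 1])
            crossings.append(float(x[i] + t * (x[i + 1] - x[i])))
            weights.append(abs(y[i]) + abs(y[i + 1]))
    if not crossings:
        return None, []
    return crossings[int(np.argmax(weights))], crossings
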