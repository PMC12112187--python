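"""Convergence-based bootstrap estimation of entropies and mutual information.

Protocol (per condition):

1. CM-centered log expression values of each gene set (CP, PES, and WES =
   CP ∪ PES as one pool) are binned on equal-width edges spanning the set's
   global value range across all time points, so the entropy is comparable
   across time as a state function.
2. At each time point, each bootstrap iteration draws ``sample_size`` genes
   with replacement and computes the plug-in entropy over ``n_bins`` bins
   (default 1000 and 30: bin count follows the square-root rule for the
   sample size).  The joint table draws CP and PES samples independently,
   pairs the i-th draws, and uses an ``n_bins`` × ``n_bins`` table whose
   marginals give an exactly non-negative mutual information.
3. Iteration means are taken at a low and a high budget (the low-budget mean
   is the prefix of the same run), the whole run is repeated ``n_runs``
   times, and the grand means are the reported estimates.  Convergence is
   declared when the mean absolute difference between the two budgets'
   grand-mean trajectories across all time points falls below
   ``convergence_tol``; non-convergence is flagged and warned, never
   silently ignored.

Derived quantities from the grand means:

* net mutual information  I_net = S(CP) + S(PES) - S(WES),
* higher-order mutual information  I_high = I_net - I(CP; PES),
* internal entropy  S_internal = S(CP, PES).

Randomness discipline: one master seed; per-run, per-set, per-time-point
substreams are spawned deterministically, so partial recomputation is
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ita.cp import CPPartition
from ita.entropy import bin_indices
from ita.matrix import ExpressionMatrix, centered_view

__all__ = [
    "BootstrapConfig",
    "EntropyTable",
    "MITable",
    "bootstrap_metrics",
    "derived_mi",
]

SETS = ("CP", "PES", "WES")


@dataclass(frozen=True)
class BootstrapConfig:
    """Fixed parameters of the convergence-based bootstrap."""

    sample_size: int = 1000
    n_bins: int = 30
    iters_entropy: tuple[int, int] = (200, 500)
    iters_mi: tuple[int, int] = (500, 1000)
    n_runs: int = 10
    convergence_tol: float = 1e-3
    seed: int = 0
    binning_range: str = "global_per_set"
    centered: bool = True

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        for name in ("iters_entropy", "iters_mi"):
            low, high = getattr(self, name)
            if not (0 < low < high):
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.binning_range not in ("global_per_set", "per_timepoint"):
            raise ValueError(f"unknown binning_range {self.binning_range!r}")


@dataclass(frozen=True)
class EntropyTable:
    """Bootstrap entropy estimates per time point for CP, PES and WES.

    ``s[X]`` are grand means at the high iteration budget (the reported
    values); ``s_low[X]`` at the low budget; ``run_s_*[X]`` hold the
    run-level replicates (n_runs, T).
    """

    time_points_min: np.ndarray
    s: dict
    s_low: dict
    run_s_high: dict
    run_s_low: dict
    converged: dict
    conv_diff: dict
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x in self.s:
            for j, t in enumerate(self.time_points_min):
                rows.append(
                    {
                        "time_min": float(t),
                        "set": x,
                        "s": self.s[x][j],
                        "s_low": self.s_low[x][j],
                        "converged": bool(self.converged[x]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MITable:
    """Joint entropy, MI and the derived net / higher-order MI per time point."""

    time_points_min: np.ndarray
    s_joint: np.ndarray
    mi: np.ndarray
    s_joint_low: np.ndarray
    mi_low: np.ndarray
    run_s_joint: np.ndarray
    run_mi: np.ndarray
    s_internal: np.ndarray = field(default=None)
    i_net: np.ndarray = field(default=None)
    i_high: np.ndarray = field(default=None)
    converged: dict = field(default_factory=dict)
    conv_diff: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_min": np.asarray(self.time_points_min, dtype=float),
                "s_joint": self.s_joint,
                "mi": self.mi,
                "s_internal": self.s_internal,
                "i_net": self.i_net,
                "i_high": self.i_high,
            }
        )
        df["converged_joint"] = bool(self.converged.get("s_joint", False))
        df["converged_mi"] = bool(self.converged.get("mi", False))
        return df


def _edges_for(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    return np.linspace(lo, hi, n_bins + 1)


def _binned(values: np.ndarray, n_bins: int, binning_range: str) -> np.ndarray:
    """(N, T) bin indices for one gene set."""
    if binning_range == "global_per_set":
        return bin_indices(values, _edges_for(values, n_bins)).astype(np.int64)
    out = np.empty(values.shape, dtype=np.int64)
    for j in range(values.shape[1]):
        out[:, j] = bin_indices(values[:, j], _edges_for(values[:, j], n_bins))
    return out


def _entropy_per_iter(binned_col, draws, n_bins, sample_size):
    """Plug-in entropy of each bootstrap iteration at one time point."""
    iters = draws.shape[0]
    b = binned_col[draws] + (np.arange(iters) * n_bins)[:, None]
    counts = np.bincount(b.ravel(), minlength=iters * n_bins).reshape(iters, n_bins)
    p = counts / sample_size
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -plogp.sum(axis=1)


def bootstrap_metrics(
    m: ExpressionMatrix, part: CPPartition, cfg: BootstrapConfig = BootstrapConfig()
) -> tuple[EntropyTable, MITable]:
    """Run the full convergence-based bootstrap on a partitioned matrix.

    Returns the entropy table (S(CP), S(PES), S(WES)) and the MI table
    (S(CP,PES), I, I_net, I_high, S_internal) with run-level replicates and
    convergence flags.  Identical seeds give bitwise-identical tables.
    """
    if part.n_cp == 0 or part.n_pes == 0:
        raise ValueError("CP and PES must both be non-empty for joint estimation")
    values = centered_view(m) if cfg.centered else m.log_values
    tp = m.time_points_min
    T = tp.size
    idx = {
        "CP": m.gene_index(part.cp_gene_ids),
        "PES": m.gene_index(part.pes_gene_ids),
    }
    idx["WES"] = np.concatenate([idx["CP"], idx["PES"]])
    binned = {
        x: _binned(values[idx[x]], cfg.n_bins, cfg.binning_range) for x in SETS
    }

    lo_e, hi_e = cfg.iters_entropy
    lo_m, hi_m = cfg.iters_mi
    run_s_high = {x: np.empty((cfg.n_runs, T)) for x in SETS}
    run_s_low = {x: np.empty((cfg.n_runs, T)) for x in SETS}
    run_sj_high = np.empty((cfg.n_runs, T))
    run_sj_low = np.empty((cfg.n_runs, T))
    run_mi_high = np.empty((cfg.n_runs, T))
    run_mi_low = np.empty((cfg.n_runs, T))

    root = np.random.SeedSequence(cfg.seed)
    run_seeds = root.spawn(cfg.n_runs)
    nb = cfg.n_bins
    for r in range(cfg.n_runs):
        cp_ss, pes_ss, wes_ss, joint_ss = run_seeds[r].spawn(4)
        for x, set_ss in zip(SETS, (cp_ss, pes_ss, wes_ss)):
            n_set = idx[x].size
            for j, t_ss in enumerate(set_ss.spawn(T)):
                rng = np.random.default_rng(t_ss)
                draws = rng.integers(0, n_set, size=(hi_e, cfg.sample_size))
                s_it = _entropy_per_iter(binned[x][:, j], draws, nb, cfg.sample_size)
                run_s_low[x][r, j] = s_it[:lo_e].mean()
                run_s_high[x][r, j] = s_it.mean()
        n_cp, n_pes = idx["CP"].size, idx["PES"].size
        for j, t_ss in enumerate(joint_ss.spawn(T)):
            rng = np.random.default_rng(t_ss)
            dx = rng.integers(0, n_cp, size=(hi_m, cfg.sample_size))
            dy = rng.integers(0, n_pes, size=(hi_m, cfg.sample_size))
            bx = binned["CP"][:, j][dx]
            by = binned["PES"][:, j][dy]
            cell = bx * nb + by + (np.arange(hi_m) * nb * nb)[:, None]
            counts = np.bincount(cell.ravel(), minlength=hi_m * nb * nb)
            counts = counts.reshape(hi_m, nb, nb)
            p = counts / cfg.sample_size
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            s_joint_it = -plogp.sum(axis=(1, 2))
            px = counts.sum(axis=2) / cfg.sample_size
            py = counts.sum(axis=1) / cfg.sample_size
            with np.errstate(divide="ignore", invalid="ignore"):
                sx = -np.where(px > 0, px * np.log(np.where(px > 0, px, 1.0)), 0.0).sum(axis=1)
                sy = -np.where(py > 0, py * np.log(np.where(py > 0, py, 1.0)), 0.0).sum(axis=1)
            mi_it = np.maximum(sx + sy - s_joint_it, 0.0)
            run_sj_low[r, j] = s_joint_it[:lo_m].mean()
            run_sj_high[r, j] = s_joint_it.mean()
            run_mi_low[r, j] = mi_it[:lo_m].mean()
            run_mi_high[r, j] = mi_it.mean()

    s = {x: run_s_high[x].mean(axis=0) for x in SETS}
    s_low = {x: run_s_low[x].mean(axis=0) for x in SETS}
    conv_diff = {x: float(np.abs(s[x] - s_low[x]).mean()) for x in SETS}
    converged = {x: conv_diff[x] < cfg.convergence_tol for x in SETS}
    et = EntropyTable(
        time_points_min=tp,
        s=s,
        s_low=s_low,
        run_s_high=run_s_high,
        run_s_low=run_s_low,
        converged=converged,
        conv_diff=conv_diff,
        n_bins=cfg.n_bins,
    )

    s_joint = run_sj_high.mean(axis=0)
    s_joint_low = run_sj_low.mean(axis=0)
    mi = run_mi_high.mean(axis=0)
    mi_low = run_mi_low.mean(axis=0)
    mt_conv_diff = {
        "s_joint": float(np.abs(s_joint - s_joint_low).mean()),
        "mi": float(np.abs(mi - mi_low).mean()),
    }
    mt_converged = {k: v < cfg.convergence_tol for k, v in mt_conv_diff.items()}
    mt = MITable(
        time_points_min=tp,
        s_joint=s_joint,
        mi=mi,
        s_joint_low=s_joint_low,
        mi_low=mi_low,
        run_s_joint=run_sj_high,
        run_mi=run_mi_high,
        converged=mt_converged,
        conv_diff=mt_conv_diff,
    )
    mt = derived_mi(et, mt)

    for name, flags in (("entropy", converged), ("joint/MI", mt_converged)):
        bad = [k for k, ok in flags.items() if not ok]
        if bad:
            warnings.warn(
                f"{name} bootstrap did not converge for {bad} "
                f"(tol {cfg.convergence_tol:g})",
                stacklevel=2,
            )
    return et, mt


def derived_mi(entropies: EntropyTable, joint: MITable) -> MITable:
    """Fill the derived identities from grand means.

    I_net = S(CP) + S(PES) - S(WES);  I_high = I_net - I;
    S_internal = S(CP, PES).  The time axes must match.
    """
    if joint.time_points_min.size != entropies.time_points_min.size or not np.allclose(
        joint.time_points_min, entropies.time_points_min
    ):
        raise ValueError("mismatched time axes between entropy and MI tables")
    i_net = entropies.s["CP"] + entropies.s["PES"] - entropies.s["WES"]
    i_high = i_net - joint.mi
    return MITable(
        time_points_min=joint.time_points_min,
        s_joint=joint.s_joint,
        mi=joint.mi,
        s_joint_low=joint.s_joint_low,
        mi_low=joint.mi_low,
        run_s_joint=joint.run_s_joint,
        run_mi=joint.run_mi,
        s_internal=joint.s_joint,
        i_net=i_net,
        i_high=i_high,
        converged=joint.converged,
        conv_diff=joint.conv_diff,
    )
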