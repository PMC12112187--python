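"""CP–PES phase-synchronization diagnostics and the entropy-production ledger.

Temporal Pearson correlations between entropy and mutual-information series
quantify how tightly the peripheral expression system tracks the critical
point; the near-identity I_net ≈ S(CP) + c (small positive offset c) is the
signature of net-MI-driven synchronization.  The self-flux of a center-of-
mass trajectory — the negative second finite difference, the "effective
force" of the genome-engine picture — is compared with the first difference
of CP entropy to test whether thermodynamic and dynamical descriptions of
the transition concur.  Finite differences are index-based (no Δt scaling)
despite uneven sampling; a Δt-scaled variant exists but is off by default.

The thermodynamic ledger applies the open-system second-law bookkeeping:
σ = ΔS(WES) − (Q/T + ΔS_matter) with σ < 0 flagged as inconsistent inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ita.bootstrap import EntropyTable, MITable
from ita.matrix import CMSeries

__all__ = [
    "DEMON_PHASES",
    "SyncReport",
    "FluxSeries",
    "ThermoLedger",
    "temporal_correlation",
    "sync_report",
    "self_flux",
    "concurrence",
    "entropy_production",
]

#: Descriptive interval labels for the three-phase feedback timeline
#: (minutes); annotations only, not computed claims.
DEMON_PHASES: tuple[tuple[str, float, float], ...] = (
    ("preparation", 10.0, 15.0),
    ("measurement", 15.0, 20.0),
    ("feedback", 20.0, 30.0),
)


@dataclass(frozen=True)
class SyncReport:
    """Phase-synchronization correlations and I_net-vs-S(CP) offset."""

    r_scp_inet: float
    r_spes_mi: float
    r_sjoint_ihigh: float
    offset_series: np.ndarray  # c(t_j) = I_net(t_j) - S(CP)(t_j)
    offset_mean: float
    sjoint_minus_ihigh_mean: float
    n_time_points: int


@dataclass(frozen=True)
class FluxSeries:
    """Self-flux (length T-2) or first-difference ΔS (length T-1) series."""

    values: np.ndarray
    time_points_min: np.ndarray  # times the entries are anchored at
    label: str = ""


@dataclass(frozen=True)
class ThermoLedger:
    """Open-system entropy bookkeeping: σ = ΔS(WES) − (Q/T + ΔS_matter)."""

    ds_wes: float
    q: float
    t_kelvin: float
    ds_matter: float
    sigma: float
    second_law_violated: bool


def temporal_correlation(x, y) -> float:
    """Pearson correlation of two equal-length time series (length ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant series")
    return float(stats.pearsonr(x, y).statistic)


def _safe_corr(x, y) -> float:
    try:
        return temporal_correlation(x, y)
    except ValueError:
        warnings.warn("correlation undefined (constant series); reported as NaN",
                      stacklevel=3)
        return float("nan")


def sync_report(et: EntropyTable, mt: MITable) -> SyncReport:
    """Correlations and offsets linking entropy and MI trajectories.

    Reports r(S(CP), I_net), r(S(PES), I), r(S(CP,PES), I_high), the offset
    series c = I_net − S(CP) with its temporal mean, and the mean of
    S(CP,PES) − I_high (the joint-entropy/higher-order-MI scaling constant).
    """
    if et.time_points_min.size < 3:
        raise ValueError("need at least 3 time points")
    if mt.i_net is None:
        raise ValueError("MITable lacks derived quantities; run derived_mi first")
    if mt.time_points_min.size != et.time_points_min.size:
        raise ValueError("mismatched time axes")
    offset = mt.i_net - et.s["CP"]
    return SyncReport(
        r_scp_inet=_safe_corr(et.s["CP"], mt.i_net),
        r_spes_mi=_safe_corr(et.s["PES"], mt.mi),
        r_sjoint_ihigh=_safe_corr(mt.s_joint, mt.i_high),
        offset_series=offset,
        offset_mean=float(offset.mean()),
        sjoint_minus_ihigh_mean=float((mt.s_joint - mt.i_high).mean()),
        n_time_points=int(et.time_points_min.size),
    )


def self_flux(cm: CMSeries, time_points_min=None, dt_scaled: bool = False) -> FluxSeries:
    """Negative second finite difference of a CM trajectory.

    flux_j = −(ε_{j+1} − 2 ε_j + ε_{j−1}) for interior points.  Deviations
    are taken from the series' overall temporal average, but a constant
    offset cancels exactly in the second difference, so the subtraction is
    omitted numerically (it would only inject float round-off).
    Affine-in-index series give identically zero flux.
    """
    eps = cm.cm
    if eps.size < 3:
        raise ValueError("need at least 3 time points for a second difference")
    if time_points_min is None:
        tp = np.arange(eps.size, dtype=float)
    else:
        tp = np.asarray(time_points_min, dtype=float)
        if tp.size != eps.size:
            raise ValueError("time axis length mismatch")
    if dt_scaled:
        d1 = np.diff(eps) / np.diff(tp)
        flux = -np.diff(d1) / (0.5 * (tp[2:] - tp[:-2]))
    else:
        flux = -(eps[2:] - 2.0 * eps[1:-1] + eps[:-2])
    return FluxSeries(values=flux, time_points_min=tp[1:-1], label=cm.gene_set_label)


def delta_series(values, time_points_min=None, label: str = "") -> FluxSeries:
    """First finite difference S(t_j) − S(t_{j−1}), anchored at t_j."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 time points")
    tp = (np.arange(v.size, dtype=float) if time_points_min is None
          else np.asarray(time_points_min, dtype=float))
    return FluxSeries(values=np.diff(v), time_points_min=tp[1:], label=label)


def concurrence(
    flux_cp: FluxSeries,
    flux_ga: FluxSeries,
    ds_cp: FluxSeries,
    window: tuple[float, float] | None = None,
    n_shuffles: int = 199,
    seed: int = 0,
):
    """Pairwise correlations among CP self-flux, GA self-flux and ΔS(CP).

    Series are aligned on shared anchor times (ΔS at t_j paired with flux at
    t_j), optionally restricted to a time window, and each pairwise Pearson r
    is accompanied by a permutation p-value from time-shuffled surrogates.
    Constant series yield missing correlations with a warning.

    Returns a DataFrame with columns pair, r, p_perm, n.
    """
    import pandas as pd

    series = {"flux_cp": flux_cp, "flux_ga": flux_ga, "ds_cp": ds_cp}
    common = None
    for fs in series.values():
        t = set(np.round(fs.time_points_min, 9).tolist())
        common = t if common is None else (common & t)
    common = sorted(common)
    if window is not None:
        common = [t for t in common if window[0] <= t <= window[1]]
    if not common:
        raise ValueError("no common time points among the series")
    aligned = {}
    for name, fs in series.items():
        pos = {round(float(t), 9): i for i, t in enumerate(fs.time_points_min)}
        aligned[name] = np.array([fs.values[pos[round(t, 9)]] for t in common])
    rng = np.random.default_rng(seed)
    rows = []
    names = list(series)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = aligned[names[i]], aligned[names[j]]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant series in pair ({names[i]}, {names[j]}); "
                    "correlation reported as missing",
                    stacklevel=2,
                )
                rows.append({"pair": f"{names[i]}~{names[j]}", "r": np.nan,
                             "p_perm": np.nan, "n": len(common)})
                continue
            r = temporal_correlation(a, b)
            null = np.empty(n_shuffles)
            for k in range(n_shuffles):
                null[k] = temporal_correlation(a, rng.permutation(b))
            p = (1 + np.sum(np.abs(null) >= abs(r))) / (n_shuffles + 1)
            rows.append({"pair": f"{names[i]}~{names[j]}", "r": r,
                         "p_perm": float(p), "n": len(common)})
    return pd.DataFrame(rows)


def entropy_production(
    ds_wes: float, q: float = 0.0, t_kelvin: float = 310.15, matter: float = 0.0
) -> ThermoLedger:
    """Second-law bookkeeping for the open expression system.

    σ = ΔS(WES) − (Q/T + ΔS_matter).  The default temperature is 310.15 K
    (37 °C cell culture).  σ < 0 is flagged as a second-law violation of the
    supplied inputs — a diagnostic, not an exception.
    """
    if t_kelvin <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    sigma = float(ds_wes - (q / t_kelvin + matter))
    return ThermoLedger(
        ds_wes=float(ds_wes),
        q=float(q),
        t_kelvin=float(t_kelvin),
        ds_matter=float(matter),
        sigma=sigma,
        second_law_violated=sigma < 0,
    )
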