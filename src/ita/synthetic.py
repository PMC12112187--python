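"""Synthetic time-series expression with the structure the analysis assumes.

The generator emulates, with ground-truth labels:

* a broad ln(nrmsf) spectrum — per-gene fluctuation scales drawn log-uniformly
  over several natural-log decades, carried by smooth low-order temporal
  profiles (microarray-like log-Gaussian residual noise on top);
* a planted critical-point (CP) band — genes whose target ln(nrmsf) falls in a
  narrow interval and whose response at the pulse time points is *bimodal*:
  genes in the upper half of the band shift coherently up, genes in the lower
  half shift down, so group-ratio curves swing above and below 1 on either
  side of the band center (a uniformly random sign split would cancel in
  group means and be invisible to ensemble-average diagnostics);
* pulse-like perturbation timing — ``hrg_like`` places the pulse mid-course
  (default 15 and 20 min, the measurement window of a fate-changing
  stimulus), ``egf_like`` confines it to the first interval (default 10 min),
  ``null`` has no temporal structure at all (baseline + i.i.d. noise), which
  is the reference condition for estimator-bias checks;
* coherent stochastic behavior (CSB) — group centers of mass stabilize as
  1/sqrt(n) with group size, by construction of independent gene profiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ita.matrix import ExpressionMatrix
from ita.variability import compute_rmsf

__all__ = ["DEFAULT_TIME_POINTS_MIN", "SyntheticSpec", "GroundTruth", "generate", "csb_check"]

#: 18 time points (minutes) of an 18-point time-course design:
#: 0..90 min, then 2 h..72 h.
DEFAULT_TIME_POINTS_MIN: tuple[float, ...] = (
    0, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720,
    1440, 2160, 2880, 4320,
)

_DEFAULT_PULSES = {"hrg_like": (15.0, 20.0), "egf_like": (10.0,), "null": ()}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    Attributes
    ----------
    n_genes
        Total gene count (default 20,000; scale down for desk-size runs).
    time_points_min
        Sampling times in minutes (default: the 18-point design).
    baseline_log_mean, baseline_log_sd
        Per-gene baseline levels on the natural-log scale (log-intensity
        like; baselines stay well away from 0 so group-mean log ratios are
        well defined).
    s_max, ln_span
        Fluctuation-scale distribution: per-gene temporal SD drawn
        log-uniformly over [s_max * exp(-ln_span), s_max], giving an
        ln(nrmsf) spectrum of width ~ln_span.
    cp_band, cp_count
        Target ln(nrmsf) interval of the planted CP genes and their number
        (at least 200 so group-level ensemble averages converge).
    mode
        ``hrg_like`` | ``egf_like`` | ``null``.
    pulse_times_min
        Pulse time points; None selects the mode default.
    pulse_amplitude_scale
        Multiplier on the band-derived response amplitude (1.0 keeps the
        planted genes' realized ln(nrmsf) inside the band).
    global_pulse_frac
        Optional genome-wide coherent shift at pulse times, as a fraction of
        each gene's fluctuation scale (default 0: off).
    noise_sd
        Residual i.i.d. Gaussian noise on the log scale.
    """

    n_genes: int = 20_000
    time_points_min: tuple[float, ...] = DEFAULT_TIME_POINTS_MIN
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    s_max: float = 2.0
    ln_span: float = 5.5
    cp_band: tuple[float, float] = (-2.6, -2.4)
    cp_count: int = 1000
    mode: str = "hrg_like"
    pulse_times_min: tuple[float, ...] | None = None
    pulse_amplitude_scale: float = 1.0
    global_pulse_frac: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _DEFAULT_PULSES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cp_count < 200:
            raise ValueError("cp_count must be >= 200 (group-level convergence)")
        if self.cp_count > self.n_genes:
            raise ValueError("cp_count exceeds n_genes")
        for name in ("baseline_log_sd", "s_max", "ln_span", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cp_band[0] >= self.cp_band[1]:
            raise ValueError("cp_band must be an increasing interval")
        pulses = self.pulse_times_min
        if pulses is None:
            pulses = _DEFAULT_PULSES[self.mode]
        pulses = tuple(float(t) for t in pulses)
        if not set(pulses) <= set(float(t) for t in self.time_points_min):
            raise ValueError("pulse_times_min must be a subset of time_points_min")
        if self.mode != "null" and not pulses:
            raise ValueError(f"mode {self.mode!r} requires at least one pulse time")
        object.__setattr__(self, "pulse_times_min", pulses)
        object.__setattr__(
            self, "time_points_min", tuple(float(t) for t in self.time_points_min)
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic matrix."""

    cp_gene_ids: tuple[str, ...]
    ln_nrmsf: np.ndarray  # realized, aligned with the matrix gene order
    pulse_times_min: tuple[float, ...]
    mode: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cp_gene_ids": list(self.cp_gene_ids),
                    "ln_nrmsf": [float(x) for x in self.ln_nrmsf],
                    "pulse_times_min": list(self.pulse_times_min),
                    "mode": self.mode,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cp_gene_ids=tuple(d["cp_gene_ids"]),
            ln_nrmsf=np.asarray(d["ln_nrmsf"], dtype=float),
            pulse_times_min=tuple(d["pulse_times_min"]),
            mode=d["mode"],
        )


def _smooth_profiles(rng: np.random.Generator, n: int, tp: np.ndarray) -> np.ndarray:
    """Random smooth profiles with zero temporal mean and unit population SD.

    Profiles are low-order in *sample index*, not clock time: a log-spaced
    time course samples densely where dynamics are fast, so consecutive
    measurements drift modestly everywhere along the design.
    """
    u = np.arange(tp.size) / (tp.size - 1)
    # sin/cos pairs of equal frequency keep the cross-sectional power
    # constant in time (sin^2 + cos^2 = 1): the background's dispersion is
    # statistically stationary, so entropy changes trace planted structure
    basis = np.stack(
        [
            np.sin(np.pi * u),
            np.cos(np.pi * u),
            np.sin(2 * np.pi * u),
            np.cos(2 * np.pi * u),
        ]
    )
    prof = rng.standard_normal((n, basis.shape[0])) @ basis
    return prof / np.sqrt(basis.shape[0] / 2.0)


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a synthetic expression matrix plus ground truth.

    Raw values are exp(baseline_i + s_i * f_i(t) + noise); identical seeds
    give bitwise-identical matrices.  In pulse modes the planted genes'
    realized ln(nrmsf) is checked against cp_band ± 0.1 and response
    amplitudes are rescaled up to 10 times before warning.
    """
    rng = np.random.default_rng(spec.seed)
    tp = np.asarray(spec.time_points_min, dtype=float)
    n, t = spec.n_genes, tp.size
    pulses = np.isin(tp, np.asarray(spec.pulse_times_min)).astype(float)

    baselines = spec.baseline_log_mean + spec.baseline_log_sd * rng.standard_normal(n)
    cp_idx = np.sort(rng.choice(n, size=spec.cp_count, replace=False))
    is_cp = np.zeros(n, dtype=bool)
    is_cp[cp_idx] = True
    bg_idx = np.flatnonzero(~is_cp)

    logx = baselines[:, None] + np.zeros((n, t))

    # fluctuation scales, log-uniform over ln_span natural-log units
    s = np.zeros(n)
    s[bg_idx] = spec.s_max * np.exp(-rng.uniform(0.0, spec.ln_span, bg_idx.size))

    if spec.mode != "null":
        logx[bg_idx] += s[bg_idx, None] * _smooth_profiles(rng, bg_idx.size, tp)

        lo, hi = spec.cp_band
        targets = rng.uniform(lo, hi, spec.cp_count)
        sign = np.where(targets >= 0.5 * (lo + hi), 1.0, -1.0)
        frac = pulses.mean()
        shape = (pulses - frac) / np.sqrt(frac * (1.0 - frac))  # zero mean, unit SD
        target_rmsf = spec.s_max * np.exp(targets)
        # pre-compensate the additive measurement noise (adds in quadrature)
        amp = np.sqrt(np.maximum(target_rmsf**2 - spec.noise_sd**2, 1e-12))
        amp *= spec.pulse_amplitude_scale
        s[cp_idx] = target_rmsf
        cp_profiles = (sign * amp)[:, None] * shape[None, :]
        logx[cp_idx] += cp_profiles

        if spec.global_pulse_frac > 0:
            logx += spec.global_pulse_frac * s[:, None] * shape[None, :]

    logx += spec.noise_sd * rng.standard_normal((n, t))

    gene_ids = tuple(f"G{i:06d}" for i in range(n))
    m = ExpressionMatrix(
        gene_ids=gene_ids,
        time_points_min=tp,
        values=np.exp(logx),
        condition_label=f"synthetic-{spec.mode}",
    )

    v = compute_rmsf(m, scale="log")
    if spec.mode != "null" and spec.pulse_amplitude_scale == 1.0:
        # keep planted genes' realized ln(nrmsf) inside cp_band ± 0.1
        for _ in range(10):
            realized = v.ln_nrmsf[cp_idx]
            off = (realized < spec.cp_band[0] - 0.1) | (realized > spec.cp_band[1] + 0.1)
            if not off.any():
                break
            bad = cp_idx[off]
            # anchor to the realized dataset maximum (a background gene)
            desired = v.rmsf.max() * np.exp(targets[off])
            scale_fix = (desired / np.maximum(v.rmsf[bad], 1e-12))[:, None]
            logx[bad] = baselines[bad, None] + scale_fix * (
                logx[bad] - baselines[bad, None]
            )
            m = ExpressionMatrix(
                gene_ids=gene_ids,
                time_points_min=tp,
                values=np.exp(logx),
                condition_label=m.condition_label,
            )
            v = compute_rmsf(m, scale="log")
        else:
            warnings.warn(
                "planted CP genes could not all be placed inside cp_band ± 0.1",
                stacklevel=2,
            )

    truth = GroundTruth(
        cp_gene_ids=tuple(gene_ids[i] for i in cp_idx),
        ln_nrmsf=v.ln_nrmsf,
        pulse_times_min=spec.pulse_times_min,
        mode=spec.mode,
    )
    return m, truth


def csb_check(
    m: ExpressionMatrix,
    group_sizes: list[int],
    n_resamples: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Coherent stochastic behavior: spread of group CMs versus group size.

    For each size n, draws ``n_resamples`` random gene groups (without
    replacement), computes each group's CM series, and reports the SD across
    groups (averaged over time points).  Under independent genes this decays
    as 1/sqrt(n); a single full-size group has zero spread by definition.
    """
    rng = np.random.default_rng(seed)
    logx = m.log_values
    rows = []
    for size in group_sizes:
        if size < 1:
            raise ValueError("group size must be >= 1")
        if size > m.n_genes:
            raise ValueError(f"group size {size} exceeds {m.n_genes} genes")
        cms = np.empty((n_resamples, m.n_times))
        for r in range(n_resamples):
            # sorted indices make the summation order canonical, so a
            # full-size "group" is bit-identical across resamples
            idx = np.sort(rng.choice(m.n_genes, size=size, replace=False))
            cms[r] = logx[idx].mean(axis=0)
        rows.append(
            {"group_size": size, "cm_sd": float(cms.std(axis=0, ddof=1).mean())}
        )
    return pd.DataFrame(rows)
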