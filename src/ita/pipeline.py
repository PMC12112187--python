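"""End-to-end orchestration: load → variability → CP → metrics → sync → map.

A single flat :class:`RunConfig` drives the whole pipeline; every artifact
(partition.json, metrics.tsv, cm.tsv, sync.json, map.tsv, manifest.json) is
written to the output directory, and the manifest records the configuration
hash, seeds, convergence flags, package versions and all warnings, so a rerun
with the same config and input is bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ita.bootstrap import BootstrapConfig, bootstrap_metrics
from ita.chromatin import delta_map, entropy_decomposition
from ita.cp import detect_cp_peaks, partition, ratio_curves, standardize_cp_interval
from ita.io import read_expression, write_metric_table
from ita.matrix import center_of_mass
from ita.sync import DEMON_PHASES, concurrence, delta_series, self_flux, sync_report
from ita.synthetic import SyntheticSpec, generate
from ita.variability import compute_rmsf, group_by_variability

__all__ = ["RunConfig", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Flat, serializable configuration of an end-to-end run."""

    input: str | None = None  # None → synthetic input
    dialect: str = "tsv"
    mode: str = "hrg_like"  # synthetic mode when input is None
    n_genes: int = 20_000
    cp_count: int = 1000
    k: int = 40
    grouping_mode: str = "equal_count"
    min_group: int = 200
    deviation_quantile: float = 0.98
    sample_size: int = 1000
    n_bins: int = 30
    nrmsf_bins: int = 80
    n_runs: int = 10
    iters_entropy_low: int = 200
    iters_entropy_high: int = 500
    iters_mi_low: int = 500
    iters_mi_high: int = 1000
    tol: float = 1e-3
    seed: int = 0
    outdir: str = "ita_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def bootstrap_config(self) -> BootstrapConfig:
        return BootstrapConfig(
            sample_size=self.sample_size,
            n_bins=self.n_bins,
            iters_entropy=(self.iters_entropy_low, self.iters_entropy_high),
            iters_mi=(self.iters_mi_low, self.iters_mi_high),
            n_runs=self.n_runs,
            convergence_tol=self.tol,
            seed=self.seed,
        )


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _versions() -> dict:
    import scipy

    import ita

    return {
        "ita": ita.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def run_all(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Stage errors are re-raised as :class:`StageError` with the stage label.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        try:
            if cfg.input is None:
                spec = SyntheticSpec(
                    n_genes=cfg.n_genes, cp_count=cfg.cp_count,
                    mode=cfg.mode, seed=cfg.seed,
                )
                m, truth = generate(spec)
                truth.to_json(out / "truth.json")
            else:
                m = read_expression(cfg.input, dialect=cfg.dialect)
        except Exception as e:  # noqa: BLE001
            raise StageError("load", e) from e

        try:
            v = compute_rmsf(m)
            g = group_by_variability(
                v, k=cfg.k, mode=cfg.grouping_mode, min_group=cfg.min_group
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("variability", e) from e

        try:
            rc = ratio_curves(m, g)
            peaks = detect_cp_peaks(rc, deviation_quantile=cfg.deviation_quantile)
            if peaks is None:
                raise ValueError("no CP detected")
            interval = standardize_cp_interval(peaks)
            part = partition(v, interval, peak_interval=peaks)
        except Exception as e:  # noqa: BLE001
            raise StageError("cp_detection", e) from e
        (out / "partition.json").write_text(
            json.dumps(
                {
                    "peak_interval": list(part.peak_interval),
                    "cp_interval": list(part.cp_interval),
                    "n_cp": part.n_cp,
                    "n_pes": part.n_pes,
                    "cp_gene_ids": list(part.cp_gene_ids),
                    "pes_gene_ids": list(part.pes_gene_ids),
                },
                indent=1,
            )
        )

        bcfg = cfg.bootstrap_config()
        try:
            et, mt = bootstrap_metrics(m, part, bcfg)
        except Exception as e:  # noqa: BLE001
            raise StageError("metrics", e) from e
        metrics = pd.DataFrame(
            {
                "time_min": m.time_points_min,
                "s_cp": et.s["CP"],
                "s_pes": et.s["PES"],
                "s_wes": et.s["WES"],
                "s_joint": mt.s_joint,
                "mi": mt.mi,
                "i_net": mt.i_net,
                "i_high": mt.i_high,
            }
        )
        metrics["demon_phase"] = [_phase_label(t) for t in m.time_points_min]
        write_metric_table(metrics, out / "metrics.tsv")

        try:
            rep = sync_report(et, mt)
            cm_cp = center_of_mass(m, part.cp_gene_ids, label="CP")
            cm_ga = center_of_mass(m, label="GA")
            fx_cp = self_flux(cm_cp, m.time_points_min)
            fx_ga = self_flux(cm_ga, m.time_points_min)
            ds_cp = delta_series(et.s["CP"], m.time_points_min, label="dS_CP")
            conc = concurrence(fx_cp, fx_ga, ds_cp, seed=cfg.seed)
        except Exception as e:  # noqa: BLE001
            raise StageError("sync", e) from e
        cm_tab = pd.DataFrame(
            {"time_min": m.time_points_min, "cm_cp": cm_cp.cm, "cm_ga": cm_ga.cm}
        )
        write_metric_table(cm_tab, out / "cm.tsv")
        (out / "sync.json").write_text(
            json.dumps(
                {
                    "r_scp_inet": rep.r_scp_inet,
                    "r_spes_mi": rep.r_spes_mi,
                    "r_sjoint_ihigh": rep.r_sjoint_ihigh,
                    "offset_mean": rep.offset_mean,
                    "sjoint_minus_ihigh_mean": rep.sjoint_minus_ihigh_mean,
                    "concurrence": conc.to_dict(orient="records"),
                    "demon_phases": [
                        {"phase": p, "start_min": a, "end_min": b}
                        for p, a, b in DEMON_PHASES
                    ],
                },
                indent=1,
                allow_nan=True,
            )
        )

        try:
            em = entropy_decomposition(m, v, bcfg, n_nrmsf_bins=cfg.nrmsf_bins)
            dm = delta_map(em)
        except Exception as e:  # noqa: BLE001
            raise StageError("chromatin_map", e) from e
        write_metric_table(em, out / "map.tsv")
        write_metric_table(dm, out / "map_delta.tsv")

        caught = sorted({str(w.message) for w in wrec})

    cfg_json = json.dumps(asdict(cfg), sort_keys=True)
    manifest = {
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": _versions(),
        "seed": cfg.seed,
        "cp_interval": list(part.cp_interval),
        "n_cp": part.n_cp,
        "n_pes": part.n_pes,
        "converged": {
            **{f"s_{k.lower()}": bool(vflag) for k, vflag in et.converged.items()},
            **{k: bool(vflag) for k, vflag in mt.converged.items()},
        },
        "convergence_diff": {
            **{f"s_{k.lower()}": et.conv_diff[k] for k in et.conv_diff},
            **mt.conv_diff,
        },
        "warnings": caught,
        "artifacts": [
            "partition.json", "metrics.tsv", "cm.tsv", "sync.json",
            "map.tsv", "map_delta.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _phase_label(t_min: float) -> str:
    for phase, a, b in DEMON_PHASES:
        if a <= t_min <= b:
            return phase
    return ""
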