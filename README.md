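# ita — information-thermodynamic analysis of time-series gene expression

`ita` is a Python toolkit for analyzing time-series genome-wide expression
(bulk microarray or RNA-seq intensity matrices) as an open stochastic
thermodynamic system. It is aimed at systems biologists studying critical
transitions in cell fate: the package ranks the transcriptome by temporal
variability, locates the **critical-point (CP) gene region**, and tracks how
entropy and mutual information flow between the CP and the rest of the
transcriptome over a stimulation time course.

## The quantities it computes

For a matrix ε of positive expression values (genes × time points, minutes),
with the natural-log view used throughout:

* **Variability axis.** rmsf_i = √((1/T) Σ_j (ε_i(t_j) − ⟨ε_i⟩)²), normalized
  by the dataset maximum to nrmsf ∈ (0, 1]; ln(nrmsf) is a time-independent
  ranking of each gene's temporal flexibility (a proxy for chromatin
  accessibility).
* **CP detection.** Genes sorted by ln(nrmsf) are split into 40 equal-count
  groups; the ratio of group-mean log expression between consecutive time
  points, ⟨ln ε(t_{j+1})⟩/⟨ln ε(t_j)⟩, exposes a narrow ln(nrmsf) window with
  bimodal singular behavior (excursions both above and below 1). That window,
  standardized to the 0.1 grid with width ≥ 0.2, splits the whole expression
  system (WES) into CP genes and the peripheral expression system (PES).
* **Entropies and mutual information.** A convergence-based bootstrap
  (sample size 1000, 30 bins, two iteration budgets, 10 repeated runs,
  10⁻³ convergence criterion) estimates per time point the Shannon entropies
  S(CP), S(PES), S(WES), the joint entropy S(CP, PES), and

      I(CP; PES)      = S(CP) + S(PES) − S(CP, PES)
      I_net(CP; PES)  = S(CP) + S(PES) − S(WES)
      I_high(CP; PES) = I_net − I

  where I_high > 0 captures redundancy/synergy beyond pairwise dependence.
* **Phase synchronization.** Temporal Pearson correlations between the
  trajectories (e.g. r(S(CP), I_net)) and the offset I_net − S(CP); self-flux
  (negative second difference of a center-of-mass trajectory, the "effective
  force") and its concurrence with ΔS(CP), with permutation p-values; the
  entropy-production ledger σ = ΔS(WES) − (Q/T + ΔS_matter) ≥ 0.
* **Chromatin-state map.** Per-gene entropy contributions credited to 80
  ln(nrmsf) bins, whose per-time-point sums equal S(WES) exactly; ΔS maps
  classify bins as unfolding (ΔS > 0) or folding (ΔS < 0), flag CP-like
  bimodal intervals, and localize the fold/unfold transition point.

A seeded synthetic generator produces matrices with the structure the method
assumes — broad ln(nrmsf) spectrum, a planted CP band with bimodal pulse
response, pulse-like vs early-only perturbation modes — plus ground-truth
labels, so every stage is testable without downloads.

## Worked example

```python
import numpy as np
import ita

spec = ita.SyntheticSpec(n_genes=6000, cp_count=500, mode="hrg_like", seed=1)
m, truth = ita.generate(spec)

v = ita.compute_rmsf(m)
groups = ita.group_by_variability(v, k=40, min_group=50)
peaks = ita.detect_cp_peaks(ita.ratio_curves(m, groups))
interval = ita.standardize_cp_interval(peaks)
part = ita.partition(v, interval, peak_interval=peaks)
print(f"CP interval: ({interval[0]:.1f}, {interval[1]:.1f})  "
      f"CP genes: {part.n_cp}  PES genes: {part.n_pes}")

et, mt = ita.bootstrap_metrics(m, part, ita.BootstrapConfig(seed=3))
rep = ita.sync_report(et, mt)
print(f"S(WES) mean: {et.s['WES'].mean():.3f}  range: {np.ptp(et.s['WES']):.3f}")
print(f"r(S(CP), I_net): {rep.r_scp_inet:.3f}   "
      f"mean I_net - S(CP): {rep.offset_mean:.4f}")
print(f"I_high range: {mt.i_high.min():.3f}..{mt.i_high.max():.3f}")
```

Output:

```
CP interval: (-2.7, -2.5)  CP genes: 447  PES genes: 5553
S(WES) mean: 2.179  range: 0.049
r(S(CP), I_net): 0.999   mean I_net - S(CP): 0.0046
I_high range: 2.661..2.771
```

The detector recovers an interval overlapping the planted band
(−2.6, −2.4); whole-system entropy stays nearly constant (range 0.05 nats
around its mean) while net mutual information tracks CP entropy almost
perfectly (r ≈ 0.999) with a small positive offset — the signature of
CP-driven phase synchronization — and the strictly positive higher-order
term shows dependence beyond the pairwise channel.

The same flow is scriptable from the shell:

```bash
ita synth --mode hrg_like --seed 42 --out matrix.tsv --truth truth.json
ita cp --input matrix.tsv --out partition.json
ita metrics --input matrix.tsv --partition partition.json --out metrics.tsv
ita run --config run.yaml          # full pipeline with manifest
```

Real datasets load with `ita.read_expression(path, dialect="tsv"|"csv"|
"series_matrix")`; hour-suffixed time labels are converted to minutes, and
zero-inflated matrices pass through `ita.handle_zeros` before analysis.

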