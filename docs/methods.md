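# Methods

This note documents the model behind `ita`, the choices that were genuinely
open when it was built, and what its synthetic benchmarks do and do not show
about real data.

## The variability axis

For a genes × time-points matrix ε (raw positive expression; natural-log view
used throughout), each gene's temporal variability is

    rmsf_i = sqrt( (1/T) Σ_j ( ε_i(t_j) − ⟨ε_i⟩ )² ),

the **population** standard deviation (divide by T, not T−1) of its
trajectory. Dividing by the dataset maximum gives nrmsf ∈ (0, 1]; its natural
log is the time-independent axis along which the transcriptome self-organizes.
`rmsf` is computed on log expression by default (a raw-scale option is kept
for sensitivity analysis). Genes that are exactly constant in time have
undefined ln(nrmsf); they are excluded from ranking with a warning, and an
all-constant matrix is a hard error. Matrices with zero entries (RNA-seq-like)
must first pass through `handle_zeros`, which replaces each zero by the
ensemble mean of n draws from Uniform(0, noise_scale) so the log transform is
defined without disturbing nonzero entries.

## CP detection

Genes are sorted by descending ln(nrmsf) and split into k = 40 equal-count
groups (equal-width intervals optional). Groups below `min_group` = 200 genes
are flagged excluded — group centers of mass only stabilize for ensembles of
a few hundred genes. At genome scale (≳20k genes) equal-count groups always
exceed 200, so the exclusion rule only bites in equal-width mode or for small
matrices; desk-scale runs lower `min_group` accordingly.

For each consecutive time pair, the ratio of group-ensemble-mean log
expression r = ⟨ln ε(t_{j+1})⟩ / ⟨ln ε(t_j)⟩ is traced along the axis
(x-coordinate: ln of the group-mean nrmsf). Ratios use **non-centered** log
values: after CM centering, group means hover near zero and their ratios are
ill-defined; centering enters only at the entropy stage.

The critical point is the narrow ln(nrmsf) window where these curves show
*bimodal singular* behavior. The detector scores each group by
max_j |r − 1|, keeps groups at or above the `deviation_quantile` (default
0.98) of scores, and then requires each candidate to be bimodal: its own
curve must swing both above and below 1, each excursion at least 25% of the
group's score. The published definition of the region is visual; this
operationalization was chosen because a pulse response necessarily produces
an entry ratio > 1 followed by an exit ratio < 1 (or vice versa) in the same
group's curve, while one-sided drifts — the typical non-critical confounder —
do not. With no qualifying group the detector returns "no CP detected", a
signal distinct from an error.

The peak interval is standardized to the reporting grid: lower endpoint
floored, upper endpoint ceiled to multiples of 0.1, then widened to a minimum
width of 0.2 in 0.1 steps, **lower edge first**. Widening lower-first keeps
endpoints on the grid (exact symmetric widening of a width-0.1 interval
would leave it) and reproduces both canonical mappings
(−2.64, −2.52) → (−2.7, −2.5) and (−2.55, −2.44) → (−2.6, −2.4), as well as
the degenerate (−2.5, −2.5) → (−2.6, −2.4). Membership in the standardized
interval is strictly open (lo < ln(nrmsf) < hi); endpoint genes belong to the
peripheral expression system (PES). CP and PES partition the genes with
defined ln(nrmsf) exhaustively.

## Entropy and mutual-information bootstrap

All entropies are plug-in histogram estimates in nats, S = −Σ p ln p, on
CM-centered log expression (toggleable to raw log). Defaults: sample size
1000 with replacement, 30 equal-width bins (square-root rule for n = 1000),
bin edges spanning each gene set's global value range across **all** time
points so the estimate is comparable across time as a state function
(per-time-point edges optional). Outliers are clamped to end bins; a
degenerate (zero-width) range puts everything in one bin, so zero-variance
input yields S = 0 exactly.

The joint table draws 1000 CP genes and 1000 PES genes independently, pairs
the i-th draws, and histograms them on a 30 × 30 grid. Marginals are taken
from the same table, which makes I = S_x + S_y − S_joint non-negative
exactly. Nothing in the protocol ties a specific CP draw to a specific PES
draw, so the single-time-point I is dominated by the finite-sample bias of
the plug-in estimator (order (B−1)²/2n nats with B the occupied bin count);
the pipeline reproduces the protocol faithfully rather than "correcting" it,
and the acceptance script reports the measured value next to an independent
brute-force bias simulation. Bias-corrected estimators are deliberately not
the default.

Iteration budgets are (200, 500) for entropies and (500, 1000) for the joint
quantities, with the low-budget mean the prefix of the same run; the whole
run repeats 10 times and grand means over runs are the reported estimates.
Convergence is declared when the mean absolute difference between the two
budgets' grand-mean trajectories over all time points falls below 10⁻³;
failure flags the table and emits a warning but never raises.

Derived identities, from grand means:

    I_net  = S(CP) + S(PES) − S(WES)
    I_high = I_net − I(CP; PES)
    S_internal = S(CP, PES)

`I_high = I_net − I` holds to machine precision by construction. The
algebraically equivalent form I_high = S(CP,PES) − S(WES) holds only up to
the mismatch between joint-table marginals and the 1-D bootstrap entropies
(small, but not zero). WES is sampled from CP ∪ PES as a single pool, so
S(WES) is estimated by exactly the same procedure as the component
entropies. Joint sampling draws fresh genes rather than reusing the 1-D
samples — the joint quantities converge more slowly and are budgeted
separately.

Randomness: one master seed spawns per-run substreams, each run spawns
per-set streams, each set spawns per-time-point streams
(`numpy.random.SeedSequence`). Identical configurations are bitwise
reproducible, and partial recomputation of any run/set is possible.

## Phase synchronization and flux

The synchronization report gives the temporal Pearson correlations
r(S(CP), I_net), r(S(PES), I), r(S(CP,PES), I_high), and the offset series
c(t) = I_net(t) − S(CP)(t) with its mean — the "I_net ≈ S(CP) + c" scaling
constant. The self-flux of a center-of-mass series is the negative second
finite difference −(ε_{j+1} − 2ε_j + ε_{j−1}); differences are index-based,
not Δt-scaled, despite uneven sampling, matching the definition as printed
(a Δt-scaled option exists, off by default). Deviations are nominally taken
about the series' temporal average, but a constant offset cancels exactly in
a second difference, so the subtraction is omitted numerically — this keeps
affine-in-index series at exactly zero flux instead of 10⁻¹⁶ round-off.
ΔS series (first differences, anchored at the interval end) and flux series
(anchored at interior points) are aligned on shared anchor times for the
concurrence table, whose Pearson correlations carry permutation p-values
from time-shuffled surrogates (199 shuffles by default).

The three-phase feedback timeline (preparation 10–15, measurement 15–20,
feedback 20–30 min) is emitted as descriptive annotations on output tables
when time points match; these are labels, not computed claims. The
entropy-production ledger σ = ΔS(WES) − (Q/T + ΔS_matter) (default
T = 310.15 K) is bookkeeping for user-supplied exchange terms; σ < 0 is
flagged, not raised. Heat and matter flows are not estimated from expression
data.

## Chromatin-state entropy map

Per bootstrap iteration, sampled genes are histogrammed (30 bins) and each
sampled gene is credited (−p_b ln p_b)/n_b — its expression bin's entropy
term divided by the bin's sampled occupancy — into the gene's ln(nrmsf) bin
(80 equal-width bins over the observed range). The occupancy-normalized form
is the unique per-sample assignment whose bin sums reproduce S exactly; the
literal per-gene term −p ln p over-counts shared bins and cannot sum to the
entropy, and is available behind `literal_contributions=True` for
comparison only. Map columns therefore conserve S(WES) per time point to
float precision, and ΔS columns telescope to ΔS(WES). A full-population mode
(every gene once, no sampling) gives the exact plug-in decomposition; the
bootstrap-averaged mode is the default for protocol consistency.

ΔS > 0 in a bin is read as chromatin unfolding, ΔS < 0 as folding. An
interval is flagged CP-bimodal when the CP window contains both a positive
and a negative ΔS excursion, each beyond `threshold_sd` (default 2) robust
SDs (1.4826 × MAD) of that interval's ΔS over all bins — the robust scale
keeps a single large excursion from masking itself. The fold/unfold
transition point is the linearly interpolated zero crossing of the ΔS
profile; with several crossings, the one flanked by the largest-magnitude
pair is reported as principal, alongside the full list; a one-signed profile
reports "no crossing" rather than erroring.

## Synthetic data: what it emulates, and what it does not

The generator produces log-Gaussian expression
exp(baseline_i + s_i f_i(t) + noise):

* **Variability spectrum** — fluctuation scales s_i log-uniform over
  [s_max e^(−ln_span), s_max] (defaults 2.0 and 5.5), giving a broad
  ln(nrmsf) spectrum like a genome-wide array.
* **Background dynamics** — smooth low-order sinusoid profiles in *sample
  index*, not clock time: a log-spaced design samples densely where dynamics
  are fast, so consecutive measurements drift modestly everywhere. The
  sin/cos pairs have constant summed power, making the background's
  cross-sectional dispersion statistically stationary; entropy changes then
  trace planted structure rather than basis artifacts.
* **Planted CP band** — target ln(nrmsf) values drawn uniformly in `cp_band`;
  the response at pulse times is a coherent shift whose sign is up for genes
  in the upper half of the band and down for the lower half. A uniformly
  random sign split would cancel inside ensemble averages and be invisible
  to group-ratio diagnostics; stratifying by band position reproduces the
  up/down peak pair flanking the region. The shift amplitude is fixed by the
  band target itself (pulse shape normalized to unit SD, noise
  pre-compensated in quadrature), so planted genes' realized ln(nrmsf) lands
  inside cp_band ± 0.1; a post-generation check rescales stragglers up to 10
  times before warning. With the defaults the band's ratio deviation exceeds
  the background's by well over the intended 5× margin.
* **Modes** — `hrg_like` pulses mid-course (15, 20 min: a fate-transition
  measurement window), `egf_like` only in the first interval (10 min),
  `null` has no temporal structure at all (baseline + i.i.d. noise), the
  reference for estimator-bias checks and the degenerate constant-gene
  limit. An optional genome-wide coherent pulse term exists but defaults to
  0 because a same-sign global shift inflates every group's ratio deviation
  and would change the planted-band detection conditions.

Not emulated: probe-level microarray physics, replicate structure,
gene–gene regulatory covariance beyond the planted band (CP and PES are
independent apart from the coherent pulse), and heat/matter exchange.
Passing tests therefore show that the pipeline recovers planted criticality
and satisfies its estimator identities under realistic noise — not that any
particular biological dataset contains a CP.

## Problem sizes

Tests and the acceptance script run desk-scale conditions: 6000-gene
matrices (3000 for the null-mode checks), 500-gene planted bands, 20 seeds
for recovery, and the full default bootstrap protocol (1000/30, (200, 500)
and (500, 1000) iterations, 10 runs) where the protocol itself is under
test; reduced budgets elsewhere. These sizes keep every stage's ensemble
properties (group sizes of ~150 genes, hundreds of genes per band) above the
coherence thresholds the method assumes while remaining quick to rerun.

## Known limitations

* Entropy values are bin-count dependent (larger bin counts give a constant
  upward offset); only within-protocol comparisons are meaningful.
* Single-time-point mutual information under this pairing protocol is
  bias-dominated; its *temporal profile*, not its absolute level, carries
  the signal.
* Temporal correlations rest on ~18 points; confidence intervals are wide,
  hence the permutation-null machinery.
* The detector assumes one CP; multi-CP landscapes and CP tracking across
  conditions are out of scope.
* Equal-width ln(nrmsf) binning of the map can leave sparse extreme bins;
  empty bins contribute 0 by definition.
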