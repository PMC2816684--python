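# Methods

## The kinetic model

Each nucleosome position is described by its methylated fraction
`M(t) ∈ [0, 1]`.  Between discrete events `M` relaxes exponentially:

    dM/dt = k_dep (1 − M) − k_dem_eff M
          = κ (M_ss − M),      κ = k_dep + k_dem_eff,   M_ss = k_dep / κ

which is solved in closed form per piecewise-constant interval
(`M(t) = M_ss + (M(t₀) − M_ss) e^{−κ(t−t₀)}`), so there is no integration
error anywhere in the package.  Three event types modify the rates or state:

- **Replication.**  At the locus's replication time the methylated fraction is
  divided by exactly `dilution_factor = 2` (H3/H4 tetramers do not split, so
  old nucleosomes are partitioned intact between the daughter duplexes and new
  nucleosomes carry no methylation).  The factor is pinned to 2 by a validator:
  it is the mechanistic ceiling of passive erasure, not a tunable.
- **Stimulus schedule.**  While an arrest stimulus is active, deposition runs
  at `k_dep_induced`; conditions can also declare classes whose stimulus
  persists through the whole course (e.g. alpha factor maintained during a
  galactose→dextrose shift), which holds those loci at their arrest steady
  state.
- **Demethylation onset lag.**  An optional `demethylation_onset_min` keeps
  `k_dem_eff = 0` until a fixed time after release (default 0).  The delayed
  demethylation sometimes seen in non-replicating releases has no known
  mechanism; the parameter exists so the phenomenon can be emulated, and
  nothing else in the package depends on it.

The effective demethylation rate composes as

    k_dem_eff = k_dem × kdem_multiplier × k_dem_scale(locus) × positional

where `kdem_multiplier` is 1 for wild type and `jhd2_scale` (default 0.25)
for the demethylase deletion, `k_dem_scale` is an optional per-locus
multiplier (locus-to-locus variability in demethylase targeting is real:
different loci show different S-phase fold drops), and `positional` is 1
within `five_prime_cutoff_bp = 500` of the TSS and `three_prime_dem_scale =
0.2` beyond it — active demethylation is targeted to the 5' ends of genes,
while 3' excess is cleared mainly by replication.

### Asymmetric recovery (`k_remeth`)

A position *below* its midlog steady state gains an extra restoration term
`k_remeth (M_ss − M)` (default 0.15/min, ~7 min e-folding).  Scientifically:
re-deposition at an active gene is co-transcriptional and fast, whereas
removal of excess methylation is demethylase-limited and slow.  Without this
asymmetry one rate constant would have to serve both directions, and the
calibrated slow decay of the arrest excess (κ ≈ 0.017/min, see below) would
leave a deep post-replication undershoot for most of a cell cycle — which is
not what synchronized courses show: within one generation the difference
distribution re-centers near zero.  The term vanishes identically for any
trajectory at or above steady state, so every closed-form and oracle result
for the decay-from-above regime is unaffected.

### Deposition tied to the baseline

By default the midlog deposition rate is derived per locus as
`k_dep = k_dem_eff · b/(1−b)`, which makes the annotated midlog baseline
fraction `b` the exact steady state of the locus (detailed balance at midlog).
This keeps un-induced loci stationary regardless of their position-dependent
`k_dem_eff`; with a single global `k_dep_mid` a 3' locus would drift toward a
steady state far from its annotated baseline.  Setting
`tie_deposition_to_baseline = False` restores the plain global-rate model
(used by the ODE-oracle tests).

### Measurement layer

The H3K4me3 channel reports `log2(M/b) + ε`, `ε ~ N(0, noise_sigma_log2²)`
i.i.d. per sample (default σ = 0.15), deterministic per
(locus, condition, channel) via CRC-derived seed streams, so subsetting or
reordering a panel never perturbs another locus's noise.  The occupancy
channel reports `log2(c/⟨c⟩)` with copy number `c` stepping 1→2 at
replication; by construction the panel mean of `2^signal` is exactly 1.

A tiling array measures ~10⁷ cells whose S phases are not perfectly aligned,
so the **measured** channels average the single-lineage trajectories over a
replication-timing jitter `N(0, sync_sd_min²)` (deterministic 9-point
mid-probability quadrature; default 4 min for the fast alpha-factor cycle,
8 min for the slower, more weakly synchronized temperature-shift cycle).  The
single-lineage truth trajectory — including its instantaneous, bit-exact
two-fold dilution — is what `methylation_trajectory` returns and what the
truth tables store; dispersion lives purely in the measurement layer.  Without
it, every background locus would show a one-sample two-fold notch at its
replication time, a sharper periodic signature than arrays ever report, and
profile clustering would organize around those notches instead of the
arrest-erasure signature.

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| `k_dem` | calibrated, ≈0.0118 /min | genome-wide demethylation rate |
| `k_remeth` | 0.15 /min | below-baseline restoration |
| `jhd2_scale` | 0.25 | demethylase-deletion multiplier |
| `three_prime_dem_scale` | 0.2 | demethylation beyond 500 bp of TSS |
| `noise_sigma_log2` | 0.15 | per-sample measurement noise |
| `sync_sd_min` | 4 (CCA) / 8 (CCTS) | population synchrony dispersion |
| cycle / S window | 60 min, 10–35 (CCA); 90 min, 30–70 (CCTS) | protocol timing |
| grid | 0–90 min, 5-min steps | sampled time points |

`k_dem` is a *derived* quantity: `calibrate_demethylation_rate` bisects for
the rate at which the no-replication erasure fraction of a reference locus
(0.5 log2 excess, mid-S replication time) is 75% of the with-replication
erasure at 90 min.  With the baseline tie, the residual ratio is monotone in
`k_dem` from 0 (pure dilution) toward 1 (instant active erasure), so the root
is unique; a target of exactly 1 is non-identifiable and raises.

Default panels: erasure-cluster ("Cluster-6-like") loci draw their arrest
excess from `N(0.5, 0.15²)` log2 (the observed 40–50% linear excess), sit
within 500 bp of a TSS, share baseline fraction 0.3, and replicate uniformly
across the protocol's S window; background loci have zero excess and spread
5'→3'.  The galactose-shutoff panel uses baseline 0.08 with ~2.5 log2
(≈5.7-fold) induction and a 3.5× demethylase-targeting multiplier — strongly
induced carbon-source genes are erased nearly completely within 75 min even
without cell-cycle re-entry, which also makes the "≥75% loss" probe filter
attainable (a locus with a 0.5 log2 excess cannot lose 75% of its linear
signal under a two-fold dilution ceiling).  A two-course panel shares loci
(and replication-order quantiles) between the alpha-factor and
temperature-shift protocols, with separate alpha- and heat-induced classes.

## Analysis procedures

- **Clustering.**  Rows are zero-centered per course (concatenated courses
  center per segment), k-means with k = 6 (Euclidean, best of 50 seeded
  restarts; rows canonicalized to id order so clustering is
  permutation-equivariant).  The focal erasure cluster is the centroid best
  correlated with a step template (high before the S-window midpoint, low
  after) — on real data this cluster is picked by eye; the template makes the
  choice reproducible.  Membership is extended with every locus whose Pearson
  correlation to the focal cluster's mean profile is ≥ 0.5, computed per
  course; zero-variance rows are excluded and reported rather than given r=0.
- **Erasure fractions.**  `E(h) = (arrest − value(h))/arrest` on the
  baseline-differenced log2 scale (0 = unchanged, 1 = full reversion, >1 =
  overshoot).  Panel-level statistics use the erasure fraction *of the
  panel-mean profile*: per-locus ratios put a noisy near-zero arrest value in
  the denominator and are heavy-tailed, so the aggregate is the headline
  metric and the per-locus median ratio is reported alongside it.
- **Replication contribution.**  `100·(1 − E_norep/E_rep)` on paired panels
  (identical loci and seeds, replication enabled vs blocked), horizon 90 min,
  averaged over 10 seeds.
- **S-phase drops** use pre-/post-window means (not single samples) to damp
  noise; drop fold = `2^drop`.
- **Drop timing.**  `drop_time` is the linearly interpolated first crossing of
  half the total loss.  On noiseless series it lands within half a grid step
  of the true replication time.  At σ = 0.15 a single noisy sample can cross
  the level early, so the replication-timing ordering analysis smooths each
  series with a 5-point running window and requires the crossing to persist
  for 2 consecutive samples (`sustain=2`); with that estimator the Spearman
  correlation between estimated drop time and true replication time is
  0.81–0.85 across seeds on 500-locus panels.
- **Positional filters** interpret "loss" on the linear scale
  (`100·(1 − 2^Δlog2)`), with boundary semantics taken literally from their
  defining rules: "over 40%" strict, "75% or more" inclusive, "log2 > 0.75"
  strict.  Running-window means use truncated symmetric windows at the edges.
  Every filter emits a report in which retained + removed exactly partition
  the input.

## What the generator does and does not emulate

Emulated: arrest-induced hypermethylation and its S-phase erasure; replication
timing as the ordering covariate; replication-blocked (cdc7-arrest-style) and
stimulus-shutoff (galactose→dextrose ± alpha hold) conditions; demethylase
deletion; the anti-phase occupancy/methylation signature of partial genomic
replication; midlog reference measurements; per-nucleosome annotation tracks.

Not emulated: probe-level hybridization physics, dye bias, and spatial array
artifacts; sequence context; mono-/di-methylation intermediates; histone
exchange as a separate channel; repeated S phases (one replication event per
trajectory — analyses at horizons near or beyond one cycle length interpret
later cycles as already at steady state); cell-to-cell variability beyond
replication-timing jitter.  Passing tests therefore certify the analysis
logic and its statistical behavior under realistic noise, not array-specific
artifacts.

Known limitation: at σ = 0.15 the correlation-extension statistic cannot
recover every low-excess, early-replicating locus — such a locus carries its
entire arrest signature in two or three pre-drop samples.  At a threshold
fixing the background false-positive rate at 5%, attainable recovery is
~0.85–0.89; at the fixed r ≥ 0.5 rule the default single-course operating
point is ≈0.78 recovery at ≈0.03 false positives (two-course union: ≈0.92 at
≈0.11).  The recovered set is therefore a high-purity, slightly conservative
sample of the true erasure class, which leaves its arrest-excess statistics
unbiased (the recovered-set mean stays inside the 40–50% band).

## Numerical choices

Closed-form piecewise trajectories (no ODE solver, no step-size tolerance);
bisection via Brent's method (`xtol = 1e-10`) for calibration with explicit
bracket checking — bracketing failure raises, nothing is clamped; ties in
replication-time sorting break by nucleosome id; k-means restarts and all
noise streams derive from one root seed (CRC32 of id/condition/channel), so
every output is bit-reproducible given the seed; matrix TSVs store floats with
`repr` and round-trip bit-exactly.
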