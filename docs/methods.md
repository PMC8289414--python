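# Methods

This note documents the models, parameters and design choices behind
`syncscope`: what the simulator generates, how the analysis operates on
it, and where the design was genuinely open.

## Synthetic islet model

### Architecture

Cells sit on a triangular lattice (lattice constant 12 µm, about one
mouse endocrine-cell diameter) jittered by Gaussian noise of sd 0.12
lattice constants and clipped to an ellipse of aspect 1.4 whose area
matches the requested cell count; the `n_cells` sites closest to the
centre are kept. Nearest-neighbour *contacts* are all pairs closer than
1.2× the median nearest-neighbour distance — the same planar adjacency
rule a section-based neighbourhood toolbox extracts.

Endocrine types are assigned in two steps. First, cells are sorted by
elliptical radius: the innermost fraction becomes β (core), and α/δ
cells are shuffled through the mantle — the canonical rodent core–mantle
arrangement. Second, a fraction `intermix` of cells, chosen at random,
has its types randomly permuted among themselves. `intermix = 0` is a
fully sorted islet; `intermix = 1` is fully random placement, emulating
architectures in which β cells have lost their preference for homotypic
neighbours. The β–β contact probability consequently decreases
monotonically in `intermix` (≈0.75 at 0.1, ≈0.56 at 1.0 with the default
75/15/10 composition).

### Calcium traces

Every cell carries a noiseless clean trace
`F(t) = 100 + 10·osc(t)` (arbitrary fluorescence units), so the
signal-to-noise ratio of a movie is `10 / noise_sd`; the default
`noise_sd = 2` gives SNR 5. The slow component of `osc` is a
tanh-smoothed square wave of duty 0.5 (softness 0.25), chosen over a
sinusoid so that "fast oscillations on the plateau" is well defined: in
`mixed` (the most common in vivo pattern) and `fast` patterns a fast
sinusoid of half the slow amplitude is gated to the slow plateau. Slow
periods are constrained to 60–620 s and fast periods to 4–31 s, the
ranges such oscillations span in vivo; defaults are 240 s and 15 s.
Note that at the default 0.1 Hz frame rate the fast component is
deliberately under-sampled (aliased), as in slow-scanned intravital
stacks.

### Synchronization domains

`n_domains = K` splits the cells into K angular sectors of equal cell
count. All domains share one oscillation frequency; their phases are a
common uniform rotation plus evenly spaced offsets `2πk/K` with ±0.2 rad
of per-domain jitter. Evenly spaced phases (rather than K independent
uniform draws) are what makes "K independent domains" a usable ground
truth: with independent phases, two domains land within the 0.7
correlation threshold of each other with probability ≈0.15 per pair, so
the generator would regularly contradict its own domain labels. The
ensemble phase is still uniform through the common rotation.

Two further properties make the domains identifiable by the analysis:

- **Interface gaps.** Transitive >0.7 merging connects any two regions
  joined by a chain of mixture signals, and a tile containing cells of
  two domains is exactly such a mixture (a 50/50 mix of two decorrelated
  sources correlates 0.707 with each). Real mosaic labelling shows
  coordinated patches as spatially disjoint; the generator reproduces
  this by rendering cells within 2.75 lattice constants of a different
  domain sensor-negative, which keeps expressing footprints of distinct
  domains farther apart than one analysis tile plus the smoothing
  kernel.
- **Stratified mosaic.** Sensor-positive cells are drawn per domain so
  every domain expresses the same number of cells
  (`sensor_fraction` of the smallest domain's pool). The K domains then
  occupy equal expressing areas, the condition under which the largest
  coordinated fraction should read 1/K.

### Waves, rendering, perfusion

A planar travelling wave (K = 1 only) delays each cell by its projected
distance along the ellipse major axis divided by `wave_speed_um_s`.
Cells are rasterised as non-overlapping discs of radius 0.45 lattice
constants on a grid of `pixel_size_um` (default 2 µm); z-planes repeat
the same cells with exponential depth attenuation (length constant
100 µm, plumbing only — the analysis never depends on it, and plane 0 is
unattenuated so emitted pixels equal clean traces exactly at zero
noise/bleach). Additive Gaussian noise, multiplicative linear bleaching
(`1 − slope·t`, clipped at 0) and clipping at `saturation_value` follow.

Perfusion movies place two straight vessels through the islet; every
tissue pixel rises with a logistic bolus (onset 10 s, τ = 1 s, amplitude
200 units over a base of 20) delayed by `perfusion_delay_s_per_um`
(default 0.15 s/µm) times its distance from the nearest vessel, with the
delay map Gaussian-smoothed (σ = 1 px) to mimic diffusion. The amplitude
is set so the whole-image mean reliably shows a >5-unit frame-to-frame
jump at arrival across vessel geometries; the per-pixel delay map is
returned as ground truth.

All generators are bit-deterministic in `(seed, config)`; the three
generators draw from independent streams derived from the one seed.

## Analysis chain

**Preprocessing.** 5×5 uniform spatial filter per frame and z-plane with
reflect padding (reflect avoids edge dimming; the border rule is
otherwise arbitrary). Pixels are excluded as *saturated* if their trace
ever reaches the saturation value and as *low fluorescence* if their
temporal mean falls below a threshold; "significant fluorescence" has no
published definition, so the default threshold is Otsu's on the
temporal-mean image — parameter-free and reproducible — and can be
overridden. Detrending removes a per-pixel least-squares line
(mean-preserving, idempotent); a per-islet-average option exists but
per-pixel is the default. The motion gate estimates rigid displacement
of every frame against frame 0 by phase cross-correlation on the
z-maximum projection and trims at the first frame displaced ≥0.5 cell
widths (default cell width 12 µm); fewer than 10 remaining frames
rejects the movie.

**Noise scale and activity.** The per-trace noise sd is estimated from
first differences using the *lower quartile* of the centred absolute
difference (scaled by 1/(Φ⁻¹(0.625)·√2)). The more common median-based
MAD estimator is inflated by aliased fast oscillatory content — which is
signal, not noise — whereas at least half of the frames of a mixed trace
lie on the quiet phase of the slow cycle and dominate the lower
quartile. Peaks are local maxima with prominence ≥2 noise sd and ≥2
frames separation; amplitude is peak value minus the 10th-percentile
baseline. A trace is *active* when its maximum peak amplitude strictly
exceeds 1.5× the **noise background**, defined as the amplitude a pure-
noise trace of the same length would show,
`σ·(√(2 ln T) + 1.28)` (expected Gaussian maximum plus the baseline
offset). Defining the background as σ itself would classify pure noise
as active, since the maximum of T noise samples sits near 3σ regardless
of σ.

**Coordination.** The masked movie is tiled into 5×5-pixel blocks (a
block needs ≥13 kept pixels); block traces are kept-pixel means,
normalised by their temporal mean and detrended. Active blocks merge
into coordinated regions; because blocks whose peaks coincide also
correlate above threshold, the final partition equals the connected
components of the strict `R > 0.7` Pearson graph over active blocks, and
that is how it is computed (a brute-force union-find over the explicit
correlation matrix is the test oracle). Spatial contiguity is *not*
required — false-colour synchronization maps colour non-contiguous areas
alike — but a `require_contiguity` flag restricts merging to adjacent
tiles when wanted. Region labels order by pixel count, ties to the
lowest member block. Active fraction = active pixels / kept pixels,
largest coordinated fraction = largest-region pixels / active pixels,
both pooled over z.

**Wave dynamics.** The islet average is the pixel-weighted mean of
active block traces; its periodogram argmax over (0, f_s/2] (DC
excluded, no bin interpolation) sets the peak frequency. Blocks
correlating >0.7 with the islet average get phases from the DFT bin
nearest the peak, taken relative to the islet average so common delays
cancel. The time lag between the maximum- and minimum-phase regions is
reported in two modes: `as_printed`, the literal published conversion
`dt = (1/f_s)·arctan(Δφ)` with f_s the sampling frequency (dimensionally
unusual — arctan of a phase — but kept verbatim for fidelity), and
`standard`, `Δφ/(2πf_peak)`, which is the mode that recovers generator
ground truth and is used for parameter-recovery checks. Speed divides
the extreme-block centroid distance (3-D, using the z spacing) by |dt|.
Speed is only reported for *eligible* islets: largest coordinated
fraction strictly >0.80 and a clear phase transition, operationalised
(no published criterion exists) as R² ≥ 0.5 of a planar fit of phase on
block position.

**Networks.** Pairwise Pearson correlation of full-length cell traces,
diagonal forced to 0, links at `R ≥ 0.95` (the figure-legend convention;
0.98 is where control-like data show a power-law degree distribution —
the calibration scan fits log₁₀ count vs log₁₀ degree over occupied bins
and accepts R² ≥ 0.9 with ≥5 bins, then checks link significance with a
circular-shift permutation null that preserves autocorrelation). Hubs
are cells linked to ≥25% of the islet (inclusive boundary, per the
figure legend; the Methods text's strict ">25%" is configurable). The
clustering coefficient is implemented exactly as published — degree
/(n−1), i.e. normalised degree — with the textbook triangle-based
transitivity also reported for comparison. Characteristic path length
sums finite shortest paths over the fixed denominator n(n−1), so
unreachable pairs dilute it toward zero rather than making it infinite;
global efficiency sums 1/L over the same denominator. In the pipeline,
per-cell traces come from the single z-plane with the greatest labelled
coverage.

**Architecture.** The four contact categories partition all typed
contacts, and probabilities are category counts over total contacts —
chosen because the published control/knockout category values then sum
to ≈1. Cohort comparisons average islets (technical replicates) per
mouse and test the per-mouse means (biological replicates); intravital
oscillation metrics instead treat islets as biological replicates
(`replicate_policy` flag).

**Perfusion.** Arrival is the first frame whose whole-image mean rises
by strictly more than 5 intensity units ("unit" taken as raw recording
units; no calibration is published). ROI distance to the nearest vessel
pixel is measured centre-to-vessel via the Euclidean distance transform;
exactly 10 µm counts as near (the published "<10"/" >10" leaves the
boundary unassigned). F/F_max is min–max normalisation over −5..+10 s
around arrival; AUC is trapezoidal over that window; dispersion is the
sample SD across ROIs at +3 s. Auto-placed ROIs are stratified by
distance class and seeded.

**Statistics.** Shapiro–Wilk (α 0.05) on each group — the published
protocol also checks normality "visually", which is not computable, so
the test alone gates; both normal → two-sided F-test on variances;
equal → Student t, unequal → Welch t; any non-normal → Mann–Whitney; all
two-sided, α 0.05 (the statistics section's "p>0.05 was considered
significant" is treated as the evident typo for p<0.05 used everywhere
else). ROUT at Q = 0.1% is reimplemented from its published description,
its host software being proprietary: constant-only robust model (median
location; RSDR = 68.27th percentile of |residuals| × n/(n−1)), residual
t-scores converted to two-sided tail p-values (df = n−1) and flagged
largest-first under a Benjamini–Hochberg-style threshold `Q·i/n`. A
validation suite measures the tree's empirical type-I error and power on
simulated pairs.

## Problem sizes and determinism

Simulated islets default to 200 cells (~210×150 µm), 512-pixel-free
frames of ~86×115 px at 2 µm/px, 60 frames at 0.1 Hz (10 min); wave
analyses use 300 frames at 1 Hz with a 60 s slow period so the recording
holds five full cycles. Recovery checks run 10–20 seeds per condition;
the statistics suite uses 2000 replicates for type-I error and 500–1000
for ROUT specificity. These sizes keep every property estimate stable at
the tolerances tested while each full run stays in the tens of seconds.
Identical `(seed, config)` reproduce every output bit-for-bit, and the
pipeline writes a manifest with a config hash (excluding the output
directory) so a run is reproducible from its manifest alone.

## What the simulator does and does not emulate

It emulates: slow/fast/mixed oscillation patterns and their in vivo
period ranges, K phase-separated synchronization domains, planar waves
of set speed, mosaic sensor expression, additive noise, linear
photobleaching, saturation, depth attenuation, core–mantle vs intermixed
architectures, and distance-delayed bolus perfusion.

It does not emulate: biophysical electrophysiology (no dual-oscillator
or Hodgkin–Huxley dynamics — waveforms are kinematic), cell-intrinsic
heterogeneity of oscillation amplitude/frequency within a domain,
non-rigid tissue motion, photon-counting noise statistics, vascular
network topology, or 3-D cell packing (z-planes resample one 2-D
layout). Passing recovery tests therefore demonstrates that the analysis
measures what it claims under controlled conditions with known truth —
not that real tissue satisfies those conditions.

## Known limitations

- The literal `as_printed` time-lag formula is not dimensionally a
  phase-to-time conversion; it is provided for fidelity and comparison,
  and all quantitative speed recovery uses the `standard` mode.
- The degree/(n−1) "clustering coefficient" equals C_avg only under the
  published definition; it is not the Watts–Strogatz quantity (also
  reported as `C_avg_transitivity`).
- With transitive merging and no contiguity requirement, any chain of
  gradually mixed signals merges its endpoints; on real data with
  continuous spatial gradients of phase the coordinated fraction is
  accordingly an optimistic estimate.
- ROUT here applies to a constant-only model (outliers of a univariate
  sample), the only case the analyses need.
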