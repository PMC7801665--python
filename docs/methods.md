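# Methods

This note documents the models and estimators in `gridnet`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not show about real recordings.

## Synthetic open-field data

**Trajectory.** A 2-D Ornstein–Uhlenbeck velocity process (correlation
time 1 s, reflective walls, 50 Hz tracking) plus a weak drift toward an
exploration goal. Goals are drawn from the least-visited 2 cm bins and
replaced once reached or after 8 s. The goal term mimics the
crumb-chasing foraging used to motivate rats in open-field recordings
and is needed for coverage: a pure OU walk at 0.15 m/s makes roughly
3–4 statistically independent visits per 2 cm bin in 20 minutes, so
~2 % of bins stay empty by Poisson statistics alone. With goal seeking,
coverage is ≥ 99 % at 20 minutes and complete at 30 minutes. The OU
scale is multiplied by a fixed calibration constant (0.80) so the
realised mean speed stays within 10 % of the request despite the goal
drift. Head direction is the motion heading plus von Mises noise
(κ = 50); two-LED geometry is not simulated.

**Grid-cell intensity.** Sum of three plane waves with wave vectors at
60° separation and magnitude 4π/(√3·spacing), rescaled to [0, 1], so
spacing, orientation, and phase are exact ground truth. Default cell:
spacing 0.4 m, peak 15 Hz, baseline 0.3–0.5 Hz, which lands the derived
statistics (specificity ≈ 0.55, information ≈ 0.35 bits/spike, burst
ratio ≈ 0.08) in the range typical of rat MEC grid cells. Spikes are
drawn by exact thinning of an inhomogeneous Poisson process with the
rate evaluated at linearly interpolated positions — no time
discretisation. Optional multiplicative theta modulation (8 Hz) and
burst injection (a seed spike becomes 2–4 spikes at 5 ms ISI) are
available.

**Multi-session protocol.** Familiar I → Novel I–III → Familiar II. In
Novel sessions all grid cells share one lattice rotation and phase
shift (coherent remapping — relative phases are preserved exactly at
the intensity level); Familiar II reuses the Familiar I map. A
random-walk phase drift (`drift_sigma`, m/√s) models destabilisation;
it can be common to the population (preserves pairwise structure) or
independent per cell (destroys it). The split into `common` vs
`independent` drift is this package's addition: the two modes separate
single-cell instability from population-level decoherence, which is
exactly what the pairwise-stability analysis distinguishes.

**LFP.** A theta oscillator with instantaneous frequency f₀ + β_f·v(t)
and amplitude a₀ + β_a·v(t) (speed v resampled to the 250 Hz analysis
clock), plus 1/f^α background noise synthesised by spectral shaping.

**Waveforms.** Two biphasic templates (trough-to-peak 0.2 ms narrow /
0.6 ms broad, 50 samples at 48 kHz) plus white noise, with ground-truth
labels.

What the generator does *not* emulate: theta-phase precession,
conjunctive grid × head-direction tuning, border cells, realistic
cluster-quality artefacts, electrode drift, and the true
trial-to-trial variability of behaviour. Passing recovery tests on
this data demonstrates estimator correctness, not robustness to every
pathology of in vivo recordings.

## Rate maps and autocorrelograms

Spike and occupancy maps are binned at 2 cm, each smoothed with the
same 2-D Gaussian (σ = 3 cm default, 5 cm variant; kernel truncated at
4σ, zero-padded boundaries), then divided bin-wise; bins with zero
smoothed occupancy get rate 0. The spatial autocorrelogram is the full
un-normalised sliding dot product (FFT-accelerated, with a direct
summation oracle). A Pearson-per-lag variant (`normalize=True`)
correlates the two overlapping segments at every lag; the raw product
carries a triangular overlap envelope plus mean cross-terms that pull
the six peripheral peaks ~5 % inward on a 1 m map with 0.4 m spacing,
so the Pearson form is used wherever grid geometry is *measured*
(spacing recovery, field-radius estimation). Gridness itself is
insensitive to the choice because it re-normalises over the masked
annulus.

Spatial correlations exclude bins unvisited in either map (the measure
should compare firing, not coverage). Within-trial stability
correlates the rate maps of the first and last 10 minutes (midpoint
split, flagged, for shorter sessions).

## Gridness, spacing, fields

Peaks of the autocorrelogram are 3×3 local maxima above 10 % of the
largest off-center peak, ordered by distance (ties broken by angle).
The central peak is masked with a disk of half the distance to the
closest peak; everything beyond 3/2 × the distance to the outermost of
the six closest peaks is masked too. The annulus is rotated by
30°…150° (bilinear interpolation; bins leaving the valid region drop
out pairwise) and the score is min(r60, r120) − max(r30, r90, r150).
Spacing is the median center-to-peak distance of the six peaks, with a
per-axis quadratic sub-bin refinement of each peak location; on
sampled 20-minute synthetic cells the 0.4 m spacing is recovered to
±0.005 m.

Field segmentation: the global field radius is 0.7 × half the distance
to the closest autocorrelogram peak; rate-map peaks closer than that
radius are pruned (lower peak loses); bins with positive Laplacian
(5-point stencil — valleys) or zero rate are excluded; remaining bins
are labelled with 8-connectivity; components under 9 bins are dropped;
components containing a surviving peak become fields (a component with
two surviving peaks counts once), sorted by mean rate.

Spatial specificity is log₁₀(FR_in/FR_out) with signed-infinity
sentinels for degenerate rates. Spatial information follows the
bits-per-spike form Σ pᵢ (λᵢ/λ) log₂(λᵢ/λ); a bits-per-second variant
(Σ pᵢ λᵢ log₂(λᵢ/λ)) is available via `per_second=True` because the
two conventions circulate under the same name.

## Spike-train statistics

CV of ISIs uses the population σ (ddof = 0; a ddof flag is exposed).
The field-pass method computes one CV per contiguous in-field
traversal (≥ 2 tracking samples, ≥ 3 spikes) and averages passes with
equal weight; the low-speed method uses segments with speed < 8 cm/s,
duration > 0.2 s, ≥ 2 spikes. Bursting: a spike with pre-ISI > 10 ms
and post-ISI < 10 ms starts a burst, both ISIs > 10 ms is a
single-spike event, everything else is uncounted; the ratio is
n_burst/n_single. Waveform features come from the deepest-trough
channel after 200× cubic upsampling; the half-width refines the
half-amplitude crossings by linear interpolation. Narrow/broad typing
is 2-means on (trough-to-peak, half-width) per experimental group,
with the smaller-trough-to-peak cluster labelled narrow.

## Tuning scores and shuffle nulls

Instantaneous rate is a Gaussian kernel density on a regular grid with
edge mass folded back, so the integral equals the spike count exactly.
The speed score correlates rate with running speed over samples with
speed in [0.02, 1] m/s (kernel σ = 0.4 s default); speed comes from
central differences of 0.1 s boxcar-smoothed positions. Head-direction
tuning is the resultant vector length of the occupancy-normalised rate
over 60 angular bins. Null distributions shift the whole train by a
uniform draw from ±30 s, wrapping circularly at the session edges (a
drop-at-edges mode exists); classification thresholds are the 95th
percentiles. A unit is a grid cell when gridness *and* spatial
information beat their nulls; speed/HD classification uses the
corresponding score; "pure speed" additionally requires not-grid and
not-HD (the exclusion rule is this package's reading of an otherwise
undefined label).

## Pairwise cross-correlations

Temporal: instantaneous rates with a 10 ms kernel at 1 kHz, z-scored;
the cross-correlogram over ±1 s is scaled by the sample count so
values lie in [−1, 1]; positive lag means the second unit fires after
the first. Spatial: z-scored rate maps cross-correlated on the torus
(wrap boundary) and scaled by bin count. Stability of a pair across
sessions is the Pearson correlation of its correlograms (2-D maps
flattened). Controls: an order-4 zero-phase Butterworth band-stop
(4–10 Hz) on the rate series, and deletion of out-of-field spikes. On
theta-free synthetic data the band-stop control shifts each pair's
stability up by ~0.05 (it removes noise-band power while the spatial
signal lives below ~2 Hz) without reordering pairs; the test suite
asserts the median shift stays below 0.1 and the ordering is
preserved.

## LFP theta analysis

Raw traces are decimated to 250 Hz with a polyphase anti-alias filter
and z-scored per session. The Morlet CWT (nondimensional frequency
ω₀ = 80, implemented via FFT with Torrence–Compo normalisation) is
evaluated on a 0.1 Hz grid; band measures use 4–12 Hz and exclude any
time sample whose band is not fully outside the cone of influence
(√2 × scale per frequency) — partially valid columns would bias peak
frequencies toward the band edge. Speed profiles are weighted
histograms over 0.02 m/s bins in [0.02, 1] m/s. The power and
frequency scores correlate 1 s-binned band power / peak frequency with
binned speed. Note the resolution trade-off of ω₀ = 80: the wavelet
integrates over ~2 s, so frequency–speed slopes are fully recovered
only when speed varies slowly relative to that window; with a 1 s
velocity correlation time the slope is attenuated, which is a property
of the estimator, not a bug. The Welch PSD theta peak is searched in
6–12 Hz (nperseg = 1024 → 0.24 Hz grid); confidence intervals use a
percentile bootstrap over recordings.

## Continuous attractor network

Exponential integrate-and-fire neurons (C_m dV/dt = −g_L(V−E_L) +
g_L Δ_T exp((V−V_T)/Δ_T) − Σ gᵢ(t)(V−E_rev,i)) on two 2π-periodic
square lattices (E and I). Conductances are β functions (difference of
exponentials, τ_rise 1 ms, τ_decay 5 ms) normalised so one event peaks
at the synaptic weight; they are integrated as two exponentially
decaying state variables. Spikes cut off at V_peak = 0 mV, reset to
V_reset = E_L = −70 mV, 2 ms refractory, 1 ms delay via a ring buffer.
E units receive independent Poisson drive (2000 Hz × 0.35 nS). Forward
Euler at dt = 0.1 ms with the exponential term clamped at V_peak;
halving dt changes population rates by well under 10 %.

Connectivity: each E unit projects with 8 nS to every I unit whose
torus distance lies in the annulus (0.7, 1.1); each I unit projects
with 30 nS to every E unit within distance 0.3 (the co-located E unit,
at distance exactly 0, is included — the open lower bound of the
connectivity rule is continuum notation, and the disc masks of
grid-based simulators include the lattice site itself). There are no
E–E or I–I connections; excitatory units interact only through
inhibition, and the competitive surround makes the sheet activity
settle into a hexagonal bump pattern within ~1 s.

These weights and radii were calibrated once by a scan until the
control sheet pattern scored gridness > 0.5; rate levels were not
tuned to any published value. Two caveats at desk scale
(40 × 40 units per population, ~2.5 s analysed per run, ~10 s wall
time): (1) ~14 bumps cannot tile a square torus hexagonally without
strain, so roughly one seed in five settles into a square/defective
state instead — sheet-pattern checks therefore aggregate the median
over three seeds; (2) bump-center units sit outside the reach of any
inhibition (the annulus+disc composite starts at distance ~0.4), so
*single-unit* peak rates are pinned at the drive-limited ceiling in
every condition. Within-field peak activity is therefore read out at
the field level: the maximum of the sheet-rate image after a σ = 1.5
lattice-unit wrap-around Gaussian smoothing, the sheet analogue of
reading peak rates off a smoothed rate map.

Perineuronal-net removal is modelled as either scaling the E→I weight
by 0.7 (`reduced_EI`) or scaling the inhibitory membrane capacitance
by 1.5 (`increased_Cm`). The capacitance factor is larger than the
~25 % increase reported in vitro because, at desk scale, a 25 % change
shifts inhibitory rates by less than seed-to-seed variability; 1.5
produces a resolvable effect with the same sign and mechanism. Both
manipulations lower inhibitory *and* excitatory median rates over
active units in ≥ 4 of 5 paired seeds — less inhibition spreads the
same drive over more, weaker units, which is the mechanism behind the
counter-intuitive excitatory-rate drop — and the increased-capacitance
variant lowers field-level peak activity relative to reduced-E→I.
Rate summaries report medians over all units and over active units
(≥ 1 spike) separately, since the appropriate inclusion rule depends
on the question.

## Group statistics

Mann–Whitney U (two-sided; exact for small tie-free samples). The
permutation test shuffles animal-to-group assignments with units
travelling with their animal; the statistic is the absolute difference
of group medians and p = (1 + #{perm ≥ obs})/(1 + n_perm). Bootstrap
CIs resample recordings with replacement (percentile interval of the
mean). Units tracked across sessions can be deduplicated to their
first recording. Repeated-measures ANOVA is intentionally not
implemented; the tidy per-unit CSV from `gridnet analyze` feeds any
standard package.

## Problem sizes used by the test suite and acceptance script

20-minute behavioural sessions for single-unit recovery; 600 s
two-session protocols with six grid cells (15 pairs) for pairwise
stability; 200 untuned cells × 200 surrogates for shuffle calibration
(100 × 200 in the script); 240 s LFP sessions; 40 × 40 attractor sheets,
4 s simulated (first 1.5 s discarded), five paired seeds. These sizes
keep the full suite and the acceptance script each within a few minutes
on a single core while leaving the tested effects well clear of their
decision thresholds.

## Known limitations

* The attractor model's absolute rate levels are calibration-dependent;
  only directions and pattern statistics are claimed.
* Hexagonal-pattern formation is stochastic at 40 × 40 (torus
  frustration); larger sheets with commensurate bump counts would
  reduce the failure rate but cost quadratic runtime.
* The two-LED head-direction pipeline and raw acquisition formats are
  out of scope; sessions enter as plain-text tables.
* Shuffle nulls assume stationarity within a session; strongly
  non-stationary firing inflates false positives.
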