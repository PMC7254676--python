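# Methods

This note documents the models and numerical choices behind `calnet`: the
synthetic-culture generator, each stage of the measurement chain, the preset
calibration, and the limits of what passing tests demonstrate.

## The synthetic culture model

A culture is a field of view of `n_rois` regions of interest (default 1000),
split into glia (`frac_glia`, default 10%), spontaneously active neurons
(`frac_active` of the non-glia cells), and silent cells. The recording
geometry defaults to 10 minutes at 20 frames/s (12 000 frames, 50 ms per
frame).

**Planted network.** Active neurons carry a planted-partition directed graph:
`n_modules` balanced modules (default 4), edge probability `p_intra` within
and `p_inter` between modules, no self-loops. The graph is ground truth for
community-recovery tests; spiking couples to it only through burst
participation (below).

**Burst schedule.** Network-burst onsets follow a renewal process with
gamma-distributed inter-onset intervals (shape 4, mean `mean_ibi`), giving a
unimodal, mildly regular IBI distribution. Each burst:

* draws a home module uniformly and samples `round(burst_participation ×
  n_active)` participants without replacement, weighting home-module neurons
  by `intra_weight` : 1. This community-weighted participation is the only
  mechanism by which the planted modules shape the spike coincidence
  structure that transfer entropy can see.
* opens with a synchronous *ignition volley*: `ceil(0.1 × n_active) + 4`
  participants spike together on the onset frame. The volley guarantees that
  a 10 %-of-active-neurons trigger opens exactly at the onset regardless of
  the background, so no igniting spike can fall outside the detected burst
  interval. The remaining participants spike at uniformly random frames
  within the following `burst_duration` seconds. Each participant fires
  `spikes_per_burst_neuron` spikes (1 for the striatal presets — the burst
  spike budget implied by the targets below allows no more).

**Isolated background.** Out-of-burst activity is a time-homogeneous point
process: the total count is Poisson with rate `independent_rate` per active
neuron, each spike is assigned to a uniformly random active neuron, and spike
frames are placed with a minimum spacing of 3 frames from one another and
from burst windows. The spacing is essential, not cosmetic: an "independent"
spike is defined as having no other spike within ±1 frame anywhere in the
system, so isolated spikes are hard-bounded by half the frame count, and a
memoryless background at a few spikes/s would lose most of its spikes to
chance coincidences (isolation probability exp(−0.15 × rate) ≈ 0.4 at
6.3 spikes/s). No time-homogeneous *independent* process can reach the
70–85 % isolated fractions that real cultures show at these rates; the
hard-core placement models the empirical fact that isolated synaptic events
are spread out in time.

**Fluorescence.** Each spike adds a non-saturating exponential transient
A·exp(−t/τ) with A = 1 %ΔF/F₀ and τ = 3 s, superposing linearly (implemented
exactly as a first-order autoregressive filter). Glia receive slow
large-amplitude waves (5–20 %ΔF/F₀, ~30 s period); silent cells only noise.
The raw trace is `baseline × (1 + (signal + drift + noise)/100)` with
per-ROI resting brightness, white Gaussian noise of `noise_sd` %ΔF/F₀ per
frame, and a slow drift: two sinusoids (120 s and 300 s periods, random
phases) plus a reflected random walk, total amplitude `drift_amplitude`.

**Movies.** `render_movie` paints disk footprints onto a smooth illumination
field (`vignette_field`) with pixel noise. The field matters: the ROI
detector normalizes the time-averaged image between its 20th and 30th
intensity percentiles, which presumes the image intensity spread is
dominated by smooth illumination/tissue structure. On a flat noise-only
background that normalization saturates ~70 % of pixels and no threshold
separates anything; somas are detectable where the local field sits below
the normalization band, so test movies place them in the dim region.

## Measurement chain: numerical choices

* **ROI detection** follows the fixed sequence (percentile clip-normalize,
  σ = 7 px Gaussian background subtraction, binarize at 0.08 directly on the
  subtracted image, fill holes, open with a 4 × 4 square, drop components
  < 10 px). Components use 8-connectivity; labels are ordered by centroid
  (row, col) for determinism. Quantiles are linear-interpolation quantiles
  throughout the package.
* **Smoothing** uses a *trailing* (causal) 5-frame boxcar. A centered window
  leaks ~40 % of a transient's amplitude into the two frames before its
  onset, which makes event detection fire early by a noise-dependent amount;
  the causal window yields a constant two-frame detection latency that
  cancels in every interval-based observable (IBI, ISI, independence gaps).
* **Baseline** F₀ is a cubic smoothing spline (`make_smoothing_spline`,
  stiffness `spline_lam = 1e6` in frame units — chosen so the fitted
  baseline bends at most once per 100 s yet still tracks the slow drift)
  through one reference point per 50 s block: the smoothed sample closest to
  the block's 10th percentile. A trailing partial block ≥ 10 s keeps its own
  reference point, shorter tails merge into the previous block. Outside the
  reference-point range the baseline is held flat (spline extrapolation at
  the recording edges is unconstrained and otherwise fabricates activity at
  frame 0). Recordings with < 5 blocks fall back to linear interpolation.
  The 10th-percentile reference biases F₀ low by ≈ 1.3 noise SD, so the
  normalized trace carries a small positive offset; the peeling criterion is
  designed to tolerate it.
* **Peeling** records a spike at the earliest frame where the residual
  exceeds θ = max(0.5 A, 2 robust-noise-SD) *and* has risen by at least
  0.35 A over the previous 3 frames. The rise requirement implements
  "onset consistent with the kernel": a smoothed transient rises by ~0.6 A
  in 3 frames while residual baseline drift rises orders of magnitude more
  slowly; without it, drift ripple produces ~10 false spikes per trace per
  10 min at the preset noise level, with it ~0.5. The noise SD is
  1.4826 × MAD of the frame difference /√2. After each detection the full
  kernel is subtracted and scanning resumes at the next frame (binary
  raster, no sub-frame refinement). A sustained 10 spikes/s cap flags
  runaway traces.
* **Classification** uses a fixed 8-feature schema (mean, variance,
  skewness, excess kurtosis, 2σ upward crossings, fraction of time above 2σ,
  power fraction below 0.1 Hz, max) and AdaBoost over depth-1 trees
  (50 rounds, seeded). The default model trains at first use on two seeded
  generator cultures (balanced classes; one sparse-firing, one regular) that
  are passed through the same baseline-normalization path as the data the
  model will see — features of spline-normalized traces differ measurably
  from ideally normalized ones.
* **Burst detection** builds the population signal as the number of unique
  neurons firing in the trailing 1 s window, applies a 10 %/5 % (of the
  recording's active-neuron count) Schmitt trigger, extends each episode
  backwards by one window so the spikes that raised the signal lie inside
  the burst interval, merges intervals closer than 0.5 s, and discards
  bursts with < 10 participants. "Active" means a neuron-labelled ROI with
  ≥ 2 reconstructed spikes per recording; the percent-active denominator is
  all cell (non-glia) ROIs. IBI is onset-to-onset. Per-burst participation
  is reported as the per-burst mean of participants/active.
* **GTE** is the plug-in transfer entropy in bits on binary states with a
  k = 2 frame past and the source's same-frame state in the conditioning set
  (instant feedback), counts over all frames, 0·log 0 = 0, no bias
  correction. Scores are clipped at 0 (floating cancellation). Edge i→j is
  significant when it strictly exceeds mean + 2 SD of the concatenated
  scores into j and out of i. Inference refuses recordings with ≤ 25 active
  neurons, with an explicit status.
* **Topology**: global efficiency on the directed graph via unweighted
  shortest paths (1/∞ = 0); Louvain (resolution 1, 10 seeded restarts, best
  modularity kept) on the undirected view of the largest weakly-connected
  component; headline Q is Newman–Girvan modularity, with the literal
  intra/inter edge-count ratio reported alongside; connector hubs are nodes
  with within-module degree z ≥ 1.5 and participation coefficient P > 0.3 on
  the union of in- and out-edges.
* **Statistics**: Tukey fences (1.5 × IQR, per group, ≥ 4 values) computed
  once from the group's values — re-deriving fences from already-filtered
  data can exclude further points, so exclusion is applied as a single pass;
  Student's t (equal variances, t = 0/p = 1 for degenerate zero-variance
  ties); classical split-plot two-way mixed ANOVA (via pingouin) with both
  Bonferroni post hoc families (treatment within genotype, genotype within
  phase) reported and labelled, since which family entered the correction is
  a reporting convention.

## Preset calibration

Presets plant the across-culture mean statistics of wild-type and HD
striatal cultures (active fraction 0.14 / 0.08, mean IBI 17 s / 24 s, global
rate 6.3 / 2.5 spikes/s, independent fraction 76 % / 84 %) and are calibrated
so that the *measured* observables of the full chain — not the raw planted
numbers — recover those values. The derivation is deterministic given the
targets:

* burst spikes per recording = (1 − independent fraction) × rate × duration,
  spread over ~duration/IBI bursts → participants per burst (27 for WT at
  one spike each; 11 for HD, just above the 10-participant detection floor);
* background spikes = independent fraction × rate × duration → the
  per-neuron `independent_rate`;
* measured participation additionally includes background spikes captured
  inside the detected burst interval (≈ rate × interval length), so the
  planted participation sits below the measured target (0.214 vs. 0.26 for
  WT).

These printed statistics are *jointly* tight: at the WT operating point the
burst-spike budget, the ≥ 1 spike/participant constraint, the capture term
and the isolation bound leave roughly a one-participant-wide feasible
window, and the HD budget (≈ 10 spikes per burst) cannot also reach the
printed HD participation (29 %) — the HD preset prioritizes the active
fraction, IBI, rate, and independent fraction, and its measured
participation comes out near 19 %.

Noise and drift amplitudes (0.05 and 0.15 %ΔF/F₀) are the conditions under
which a 1 %-amplitude kernel chain reproduces those joint statistics: at
larger values, per-trace detection latency jitters by ±1 frame (driven by
residual baseline-tracking error), which collapses isolated-spike gaps and
desynchronizes burst volleys enough that HD bursts fall below the
10-participant floor. They correspond to high-quality soma-averaged
recordings.

`intra_weight` is calibrated per preset (WT-STR 20, HD-STR 4, default 3)
against the topology targets: the WT effective networks then have global
efficiency ≈ 0.22 ± 0.01 and the HD networks Louvain Q ≈ 0.59 ± 0.01
(means ± SEM over 10 cultures). The inter-culture variability structure is
not constrained by across-culture means; presets expose a `culture_cv`
multiplier (default 0 — cultures differ only through seed noise).

## What the round trips do and do not show

Passing recovery tests show that the chain is *self-consistent at
calibration*: the detector/estimator stack returns the statistics the
generator planted, through rendering, baseline estimation, classification
and reconstruction. They do not validate the chain against real indicator
nonlinearity (saturation, Ca²⁺ buffering), motion, neuropil contamination,
overlapping somas, non-stationary firing, or electrophysiological ground
truth — all explicitly out of scope (no motion correction, no demixing, no
saturating-indicator model).

Known limitations of the generator at the calibrated operating point, all on
observables outside the recovery targets: the WT effective networks are more
modular than real WT cultures (Louvain Q ≈ 0.7 vs. ~0.5) because strong
community weighting is the only lever that reaches the efficiency target;
GTE graphs at ~2–4 % density have no nodes passing the z ≥ 1.5 / P > 0.3
cartography jointly, so connector-hub counts are near zero; and Louvain
fragments the sparse HD graphs into communities of ~9 rather than ~16
neurons. A richer coupling model (e.g., directed within-burst propagation
along planted edges) would be needed to move these jointly with the targeted
observables.

## Problem sizes

Recovery studies use 10 cultures per preset of 1000 ROIs × 12 000 frames,
the scale of one real field of view; property oracles run on deliberately
small inputs (≤ 10 neurons for exhaustive transfer-entropy histograms,
≤ 50 nodes for Floyd–Warshall, 8 nodes for exhaustive-partition modularity)
where brute force is exact.
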