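# Methods

`prebotseq` reconstructs, as a reusable and fully testable pipeline, the
analysis of cell-type-dependent activation sequences during rhythmic
bursting in the preBötzinger complex (preBötC): from a calcium-indicator
movie and a local field potential (LFP) to per-cycle activation orders and
cell-type-level timing statistics. Because no raw recordings of this kind
are publicly deposited, the package ships a first-class synthetic-data
generator with known ground truth; every pipeline stage is scored against
that truth.

## Signal model and pipeline

**LFP conditioning.** The raw electrode signal (digitized at ~10 kHz) is
full-wave rectified and smoothed with a single-pole exponential integrator,
time constant τ = 0.15 s (midpoint of the conventional 100–200 ms range;
the exact discretization `y[n] = y[n-1] + (1 - e^(-Δt/τ))(|x[n]| - y[n-1])`
makes the step response `A(1 - e^(-t/τ))`, which tests verify in closed
form). The integrated trace is decimated to the imaging frame rate through
a zero-phase Chebyshev type-I order-8 low-pass with cutoff at 0.8× the
frame-rate Nyquist. Two numerical choices differ from a naive
implementation: the filter runs as second-order sections (the transfer
function of an order-8 filter whose cutoff is 4·10⁻⁴ of the sample rate is
numerically singular in polynomial form), and its numerator is rescaled to
exact unit DC gain, because an even-order Chebyshev's passband ripple
applied forward–backward would bias a constant input by ~0.1–1%. Padding
of 3/cutoff seconds suppresses edge transients. Sampling at the frame
trigger times uses linear interpolation.

**Movie conditioning.** Each pixel's time series is band-pass filtered at
0.025–1.5 Hz with a third-order zero-phase (forward–backward) Butterworth
filter, then frames are smoothed with an unweighted 3×3 spatial mean whose
kernel shrinks at the borders (so padded values never leak into edge
ROIs). Reflect padding of 6/low-cut seconds is used: the slowest
high-pass pole settles with τ ≈ 2/(2π·0.025 Hz) ≈ 13 s, and this padding
drives edge asymmetry below 10⁻⁶ relative, making the operator
time-reversal symmetric to float precision (a property test).

**Functional ROI detection (maxCC).** For every pixel the maximum, over
lags 0–40 frames (positive lag = calcium trailing the LFP), of the Pearson
correlation between the pixel trace and the integrated LFP is computed
(maxCC), together with the argmax lag; ties resolve to the smallest lag
and zero-variance overlaps contribute correlation 0. The image-wide
computation is vectorized (one matrix product per pixel block over a
matrix of lag-shifted LFP windows, with cumulative sums supplying the
per-lag means and norms) and is verified to agree with the scalar
definition to 10⁻⁹ and with a brute-force double-loop oracle exactly.
Pixels above the detection threshold (maxCC > 0.2) are grouped by
8-connected labelling; components of at least 9 px yield one 7×7 ROI at
the component's maxCC peak, shifted inward by up to 3 px if the window
would clip the border; candidates are accepted greedily by descending
maxCC with centres at Chebyshev distance ≥ 7 px. The published workflow
placed ROIs partly by eye; this deterministic rule replaces the human and
a QC overlay is intended for review.

**Spectral unmixing.** The 3-excitation × 3-emission reference stack is
flattened to a 9 × pixels matrix and factorized V ≈ WH with non-negative
W (spectra) and H (abundance maps) by multiplicative updates minimizing
squared Frobenius error; the objective is provably non-increasing per
sweep (asserted per iteration in tests) and W columns are rescaled to
unit sum with the inverse scale absorbed into H. Two ambiguities require
care. Permutation: components are matched to a documented expected
signature table (calcium dye / EGFP / tdTomato) by greedy cosine
similarity. Non-uniqueness: when all spectra are strictly positive, even
an exact factorization is not unique — a signature can absorb a scaled
copy of another with the abundances compensating. The unmixer therefore
runs guided: one restart warm-starts at the expected signatures with
their non-negative least-squares abundances (an exact factorization is a
fixed point of the updates), four more restart randomly, and residual
ties (within 0.1%) break toward expected-signature similarity. If the
reference table mismatches the data the random restarts win on residual,
so the guidance cannot force a bad fit. A cell's reporter flags (EGFP →
glycinergic, tdTomato → GABAergic) are positive when the mean abundance
inside its 7×7 ROI exceeds the background mean + 2 SD (background = all
pixels outside every ROI) **and** reaches 0.75× the cell's calcium-dye
abundance in the same window. The relative criterion matters: spectral
bleed-through between the green dye and EGFP scales with cell brightness,
so on bright cells it clears any background-derived threshold; judging
the reporter against the cell's own brightness is what visual
classification — which this rule replaces — effectively does. Both
constants are configurable.

**Cell typing.** Cells split into Regular (maxCC strictly above a cutoff)
and Irregular. The cutoff is per-experiment in the original workflow
(range 0.47–0.64, tuned by hand); here it is suggested automatically by
maximizing the between-class variance of the detected cells' maxCC sample
(Otsu's criterion evaluated exactly at sample midpoints, no histogram
binning), clamped to [0.40, 0.70] with a warning, and always overridable
in config. With at least 6 detected cells required. The five types are:
R-Ex (no reporter, regular), R-Gly (EGFP, regular), Irr-Ex (no reporter,
irregular), Irr-Gly (EGFP, irregular), Irr-Cotrans (EGFP + tdTomato,
irregular). The three reporter/regularity combinations never observed in
slices map to `Unclassified`, kept in outputs but excluded from five-type
statistics. Composition tables print counts and percentages
(100·count/row-total, rounded half-up to one decimal — half-up, not
banker's, so 31.25 prints as 31.3).

**Burst events.** The frame-aligned integrated LFP is detrended with a
10 s moving median (tracks drift, steps over bursts) and peaks are
accepted when both height and prominence exceed 0.8× the SD of the
detrended trace, with a 1 s minimum spacing keeping the larger peak. The
prominence requirement goes beyond the bare amplitude rule; it stands in
for the visual confirmation step of the original workflow by rejecting
noise ripples on slow shoulders. Sigh-like bursts — amplitude above 2×
the median burst amplitude (a configurable rule of this package's design;
the phenomenon is described only qualitatively in the literature) — are
flagged and excluded from sequence analysis, never silently dropped.

**Activations and cycles.** For each cell and each accepted burst, the
candidate activation is the largest local maximum of the cell's filtered
ROI trace within ±24 frames of the LFP peak; it counts as an activation
when it exceeds k·σ (k = 3) where σ is 1.4826 × the median absolute
deviation of the cell's trace on frames farther than 24 frames from
*every* detected burst peak. Rejected sigh bursts are excluded from the
noise sample as well: their windows carry the largest calcium transients,
and at ~5 s cycles with a ±2.4 s window they would otherwise constitute
most of the "inter-burst" frames and inflate σ several-fold for regular
cells (measured: regular-cell recall drops from >0.95 to ~0.4). Timing is
(peak frame − LFP peak frame)/rate, negative when the cell leads the
population. A cycle enters the sequence analysis only when at least 50%
of the classified five-type cells activated. Within an included cycle,
cells sort by timing (ties by cell id, logged), and position i of N maps
to percent rank 100·i/N ∈ (0, 100] — the denominator is the cycle's
activated-cell count, which keeps cycles with different participation
comparable; the alternative reading (slice total as denominator) can be
selected in code but is not the default.

**Group statistics.** All sequence summaries are computed per slice and
then averaged (mean ± SE, n = slices): occupancy of each type per 10%
rank bin (share of that bin's activations), per-type cumulative
activation probability over rank bins, leader fractions (type of the
first activation per cycle), early-activation fractions (cycles with ≥ 1
activation at or before −0.5 s / 0 s), and per-type mean timing.
Cross-type comparisons use one-way ANOVA on slice-level values with Tukey
HSD post hoc (statsmodels), and pairwise two-sample Kolmogorov–Smirnov
tests (scipy, asymptotic p) reported raw in three families: pooled
activation timings, per-slice per-bin occupancy shares, and pooled
percent ranks. No multiplicity correction is applied to the KS family by
default, matching the original reporting convention. Degenerate ANOVA
inputs (all groups identical) return F = 0, p = 1; zero within-group
variance with distinct means raises.

## The synthetic generator

The generator emulates a rhythmic slice experiment at a scale a single
CPU can analyze end-to-end in minutes:

- **Geometry:** 96×96 px field (≈2.6 μm/px over a 250 μm field — the
  pixel grid is coarser than the 256×256 acquisition it emulates; ROI and
  cell sizes are kept at the native 7×7 px scale so the detection
  geometry is unchanged). Cells are soft disks of radius 3 px on a
  jittered grid with ≥ 9 px separation.
- **Rhythm:** 120 bursts at 5 ± 0.8 s; the LFP is enveloped wideband
  noise (Gaussian envelope, SD 0.12 s) over a small noise floor, 10 kHz.
  Sighs occur with probability 1/12 per burst and scale the envelope and
  the calcium response ×2.5, adding a doublet calcium peak 0.6 s later.
- **Cell types (per slice):** 10 R-Ex, 4 R-Gly, 10 Irr-Ex, 4 Irr-Gly,
  2 Irr-Cotrans, 6 non-rhythmic distractors — proportioned like the
  pooled composition of the five reported slices at ~30 rhythmic cells.
  Mean timing offsets follow the reported per-type means (Irr-Gly 81 ms,
  Irr-Ex 102 ms, R-Ex 225 ms, Irr-Cotrans 290 ms after the LFP peak);
  R-Gly, for which no mean is printed, is set to 180 ms, between the
  groups and before R-Ex, consistent with the reported cumulative-curve
  ordering. The published ± values are SEs across slices; per-cycle SDs
  here are 150 ms (regular) to 230–250 ms (irregular), broad enough that
  the cycle-to-cycle order is genuinely stochastic.
- **Regular vs irregular phenomenology:** regular cells activate with
  p = 0.95 and amplitude 20 ± 4; irregular cells with p = 0.60–0.65 and
  amplitude 8 ± 2.5. Participation, amplitude and timing jitter — not a
  label — are what drive the maxCC split the classifier recovers.
- **Calcium kinetics:** double-exponential kernel, rise 80 ms, decay
  1 s (typical somatic kinetics for a bulk-loaded green calcium dye at
  ~10 Hz sampling); the ground-truth offset of an activation is the peak
  time of its noiseless transient.
- **Spectra:** the reference stack is `mixing_matrix @ abundances` plus
  noise, with the dye on all cells, EGFP on glycinergic and co-transmitting
  cells, tdTomato on co-transmitting cells only. The 9×3 signature table
  is plausible for (720, 800, 900 nm) excitation × (475/50, 531/40,
  641/75) emission but is not calibrated against dye libraries.

What the generator does **not** model: photon-level optics (noise is
Gaussian, not Poisson), motion artifacts, neuropil contamination, dendritic
signals, burstlet-only events, slow indicator bleaching, and any network
dynamics (cells are conditionally independent given the burst train).
Passing recovery tests therefore demonstrates that the analysis recovers
the statistical structure it assumes, under realistic noise and timing
jitter — not that it is robust to every artifact of real two-photon data.

## Scoring conventions

ROIs match planted cells within Chebyshev distance 2 px; detected bursts
match true bursts within 0.3 s. Timing recovery is the pooled Pearson
correlation and mean absolute error between recovered activation timings
and the generator's true calcium-peak offsets over all matched
(cell, burst) pairs. Under the default five-slice conditions (seeds 1–5)
the pipeline reaches ~93% ROI recovery, 100% regularity recovery, pooled
timing r ≈ 0.94 with MAE ≈ 0.4 frames, and reproduces the configured
ordering of per-type mean timings; the rare large timing errors come from
cycles whose neighbouring burst falls inside the ±24-frame window, where
the largest-local-maximum rule can capture the neighbour's transient — a
known estimator limitation shared with the original definition.

## Problem sizes

Defaults were chosen so that one slice (≈6000 frames × 96×96 px) runs the
full analysis in ~25 s and the five-slice study in ~2.5 min on one core;
the pixel count, not the statistical structure, is the only dimension
scaled down relative to the emulated acquisition.

## Known limitations

- The ±24-frame activation window spans nearly half a 5 s cycle;
  short inter-burst intervals can let a neighbouring transient win the
  largest-local-maximum rule (see above).
- At ~10 Hz, onset times cannot be estimated reliably; peak timing is the
  activation marker throughout, and no sub-frame interpolation is done.
- The regular/irregular cutoff suggestion assumes a roughly bimodal maxCC
  sample; unimodal samples are clamped with a warning and should be set
  manually.
- KS p-values are asymptotic; with the pooled sample sizes involved this
  is adequate, but exact p-values for very small types (co-transmitting
  cells in sparse slices) are not attempted.
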