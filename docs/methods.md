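# Methods

`statekit` reimplements, as a tested library, the computational pipeline
used to quantify how brain states — wakefulness, NREM/REM sleep, and three
anesthetic regimes — reshape hippocampal CA1 activity across four
observation levels: the local field potential (LFP), sorted single-unit
spike trains, two-photon calcium imaging, and longitudinal dendritic-spine
imaging. The package is exercised end to end on synthetic data whose
ground truth is known by construction; this note records the models, the
defaults, the numerical choices, and what the synthetic conditions do and
do not establish about real recordings.

## LFP analysis

**Filtering and spectra.** All band-limited operations use third-order
Butterworth filters applied forward and backward (zero phase,
`sosfiltfilt`). Spectra are Welch averages over 30-s windows with 15-s
overlap, giving 1/30 Hz resolution. The relative-change index between two
conditions is (a − b)/(a + b), bounded in [−1, 1] for non-negative inputs
and antisymmetric in its arguments.

**Aperiodic 1/f exponent.** The exponent is the slope of a robust
(iteratively reweighted, Tukey biweight) straight-line fit of log10 power
over the 30–50 Hz band. The default abscissa is log10 frequency, which
makes the slope of an exact P(f) = f^−β spectrum equal −β; a
linear-frequency abscissa is available via `log_freq=False`, since the
source description of the fit leaves the abscissa open. Non-positive
power bins are excluded before taking logs.

A point worth recording: the 30–50 Hz slope of a *single realization* of
1/f^β noise fluctuates around −β with a spread set by the total recording
duration (the realization's random Fourier amplitudes are fixed, so
averaging more Welch windows of the same signal does not remove them).
At 15 min of signal the estimator is within ±0.2 of β ∈ {1, 2, 3} for
every seed we test; at 3 min, occasional ±0.27 excursions occur. The
recovery checks therefore use 15-min synthetic recordings.

**Active periods.** Detection follows a hysteresis scheme adapted from
ripple detectors: the 4–20 Hz band-passed signal is rectified and
boxcar-smoothed (10 ms default), and in parallel its smoothed square is
z-scored. A sample is active if either detector marks it — the absolute
detector seeds where the envelope exceeds 15 μV and extends to 7 μV, the
relative detector seeds at 2 z-units and extends to 1 z-unit. Resulting
periods are merged when separated by less than 900 ms and discarded when
shorter than 500 ms, in that order; the active fraction is reported per
15-min half-open bin aligned to the recording start, the trailing partial
bin with its own duration. The implementation is vectorized but is tested
to be boundary-exact against a literal sample-by-sample state machine on
randomized signals.

**Phase–amplitude coupling.** For each cell of a 0.1–8 Hz phase grid ×
20–100 Hz amplitude grid (bin widths 1 Hz and 10 Hz by default, both
configurable; 0.5 Hz phase bins reproduce the finer grid), both
components are narrow-band filtered, the analytic phase and amplitude
extracted, the amplitude binned into 18 phase bins, and the modulation
summarized as (max − min)/(max + min) of the bin means. Significance is
assessed per cell against 200 circular time-shift surrogates of the
amplitude envelope (minimum shift 1 s) at α = 0.05; non-significant cells
are reported as 0. Cells whose mean band amplitude is below 10⁻³ of the
signal SD are also reported as 0: with no measurable fast rhythm the
scale-invariant modulation statistic would otherwise amplify pure filter
leakage (a pure low-frequency sine would show spurious "coupling" at its
harmonics). Note that a *perfectly periodic* amplitude modulation is
invariant under circular shifts, so the surrogate test has no power
against it; the detection example therefore adds broadband noise, and the
false-positive calibration uses white-noise inputs. A modulation whose
frequency falls on a grid-bin edge (1 Hz with 1-Hz phase bins starting at
0.1 Hz, or 40 Hz with 10-Hz amplitude bins) splits its coupling evenly
between the two adjacent cells; localization checks accept either
neighbor.

## Spike-train analysis

**STTC.** The spike time tiling coefficient of trains A and B over a
recording [0, T] is

    STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]

with P_A the proportion of A's spikes within ±Δt of any B spike and T_A
the proportion of [0, T] tiled by the union of ±Δt windows around A's
spikes, overlaps counted once and edges clipped. Empty trains and
vanishing denominators yield missing values rather than exceptions;
downstream distributions omit them. The implementation is exact against
a brute-force double-loop oracle to 1e-12.

The STTC's selling point is insensitivity to firing rate. The
rate-insensitivity check contrasts it with a Pearson correlation of
200-ms binned counts on pairs that share both spike-level coupling and a
slow (0.5 Hz, full-depth) common rate modulation: regenerating the pair
at 25–100% of the base rate moves the mean STTC (Δt = 10 ms) by < 0.05
while the count correlation falls by several times that, because the
co-modulation term in the count covariance scales with rate.

**PPC.** Pairwise phase consistency of a unit's spike phases is the mean
cosine of all pairwise phase differences, computed in closed form from
the resultant vector, ((Σcos)² + (Σsin)² − n)/(n(n−1)); it is unbiased
under uniform phases and invariant to global rotation. Phases are read
from the analytic signal of the band-passed LFP at spike times.

**Population-rate power.** Unit trains are summed into a 1-ms binned
population vector; each 30-s window's periodogram (Hann) is divided by
that window's mean firing rate before averaging, which makes the spectrum
of a homogeneous Poisson population flat and rate-invariant. Windows with
no spikes are skipped.

**Active units.** A unit is active in a 15-min bin if it fires at least
5 times there; per-bin counts are reported as fractions of a reference
bin (the pre-anesthesia wakeful interval in the original design).

## Calcium analysis

Traces are corrected as F′ = F − 0.7·F_neu. Optional dF/F uses a rolling
8th-percentile baseline over 60 s (the upstream solver's internal
baseline is not reproducible here); ROIs with non-positive baselines are
excluded. Transients are `find_peaks` maxima with height 200, minimum
distance 10 frames, and prominence 200 (all sweepable; a threshold sweep
mode supports the robustness analysis over 50–700 a.u.).

**Decay constants.** The per-ROI decay constant τ is estimated from the
10 best-isolated transients — "best isolated" formalized as the largest
minimum gap to neighboring transients, ties broken by larger prominence.
Each contributes a constrained single-exponential fit of the post-peak
segment (to the next transient or 2 s, whichever is shorter); the ROI's
τ is the median of the fits, and τ > 2 s is treated as failed extraction.
This replaces the original sparse-deconvolution fit; only τ feeds
downstream. An AR(1)-style alternative estimates the frame-to-frame decay
factor g from the lag-2/lag-1 autocovariance ratio of the segments
(τ = −Δt/ln g). The moment ratio rather than a lag-1 regression matters:
regression on noisy observations is attenuated toward 0 (we measured
τ̂ ≈ 0.29 for a true 0.7 at SNR 10), while the lag ratio cancels white
measurement noise, which only contaminates lag 0.

**Correlations and population metrics.** Pairwise Pearson or Spearman
coefficients of z-scored traces are Fisher-transformed (arctanh) after
clipping |r| at 1 − 1e-7; diagonals are excluded, quartile occupancies
and an optional |z|-versus-centroid-distance profile in 25-μm bins are
reported. Population coupling is the leave-one-out correlation of each
z-scored trace with the sum of the others. Population power is the Welch
spectrum of the summed z-scored traces with segment length = FFT length
= 1024 samples and no overlap (~34 s at 30 frames/s); the printed
description of a 1-s window is inconsistent with the 0.1–0.2 Hz
population peak this analysis is meant to resolve, so the FFT length was
taken as the segment length. Recovery trajectories are per-metric medians
normalized to the awake-baseline median, after dropping ROIs with no
detected peaks and ROIs with τ ≤ 1 frame (noise-peak artifacts).

## Cross-session registration and identity

Session alignment evaluates four candidates — {rigid, affine} × {mean,
enhanced-mean image} — scoring each by d = Σ (x_ref − x_aligned)² over
the central region (10% of each dimension cropped per border). A
candidate is eligible only if more than 90% of the central region is
covered by warped data; among eligible candidates the smallest d wins.
The transform fitter itself (Powell over the parameters, seeded by phase
cross-correlation and, for affine, by the fitted rigid solution) is
deliberately pluggable: only the score, the guard, and the selection are
contractual.

ROIs of aligned sessions match when centroids are within 3 μm and pixel
overlap exceeds 70%; overlap is intersection-over-union (the smaller-ROI
denominator is available via configuration). One-to-one conflicts resolve
greedily by descending overlap, ties by centroid distance. Global IDs are
assigned sequentially: the reference recording seeds the ID range, each
later ROI inherits the ID of its best match among all previously
processed ROIs or receives a fresh one; the assignment is deterministic
in the recording order and a global ID appears at most once per
recording.

## Ensemble structure

All fragmentation metrics operate on time × neuron matrices matched
across conditions: five independent subsamples of N_min neurons,
down-sampled 30 → 10 Hz (mean-binning for raw traces, sum for
deconvolved), metrics reported as medians over the five draws.

- **PCA**: number of components to 90% cumulative variance, plus the
  log-log slope of variance explained over the first 100 components.
- **tSNE density clusters**: perplexity 5–45 (step 5) chosen by minimum
  final embedding cost; 30-component linear pre-reduction; Euclidean
  metric for raw signal, cosine for deconvolved. The 2-D embedding
  becomes a 100×100 occupancy histogram, Gaussian-smoothed with
  SD = extent/40, rolling-ball background-subtracted (radius 50 bins),
  3×3 median-filtered, Otsu-thresholded, watershedded from
  extended-maxima markers (depth 20% of the smoothed maximum), and the
  resulting objects counted. The rolling-ball radius must exceed the blob
  scale — a radius smaller than a blob subtracts the blob itself — and
  counts are comparable only within a fixed configuration.
- **Affinity propagation**: similarity is the cosine similarity between
  time points, input preference the median of that matrix, damping 0.9
  (the solver fails to converge on near-duplicate observations at lighter
  damping); the exemplar count is reported with a convergence flag.
- **Signed Louvain**: community detection runs on full, unthresholded
  Fisher-transformed correlation matrices using asymmetric signed
  modularity — positive and negative weights get separate configuration
  null models and the negative term is down-weighted by v⁻/(v⁺ + v⁻) —
  optimized by standard greedy node moves with graph aggregation, 10
  restarts per resolution value, maximum-Q partition kept, over
  γ = 0–3 in steps of 0.1. This component is written in-package because
  no installed library provides the signed asymmetric null model.

The state-contrast generator for these metrics builds a cyclic state
sequence with random dwell lengths (every state visited, occupancy
balanced) and zero-mean state activations. Two pattern families are
provided, and they deliberately decouple two axes that a naive emulator
ties together. *Assembly* patterns split neurons into co-active groups —
distinct temporal states **and** crisp correlation blocks; with block
loadings, tSNE separability and within-block correlation both scale as
(coupling/noise)², so one cannot have many resolvable temporal states
with weak correlations. *Distributed* patterns give every state a dense
random loading over all neurons: the population vectors of different
states stay far apart (strong temporal-state structure for PCA, tSNE and
affinity propagation) while time-averaged pairwise correlations are near
zero (no modular structure for Louvain).

The wake-like condition is 3 assemblies with coupling 1.0, noise SD 0.5
and ~3-s dwells; the anesthesia-like condition is 20 distributed
microstates with coupling 1.2, noise SD 0.6 and ~0.8-s dwells. This
instantiates the contrast — few long-lived coherent ensembles against
many short-lived fragmented microstates — in a form every statistic can
resolve, and structurally forces the direction: more PCA/tSNE/AP
clusters, more Louvain communities (compared as the median count over
the γ = 0.1–3 scan; wake stays pinned at its assembly count while the
unstructured anesthesia matrix fragments increasingly with γ), and lower
modularity at γ = 1 under the anesthesia-like condition.

Three emulator artifacts are worth recording because they dominated the
design. First, non-centered (all-positive) state activations give every
time point a shared baseline; cosine similarities then saturate and tSNE
embeddings grow bridges between states — centering the activations
removes both. Second, with two balanced states exactly half of all
time-point pairs are within-state, so the affinity-propagation input
preference (the *median* similarity) sits on the boundary of a bimodal
distribution and the exemplar count becomes bistable; three or more
balanced states keep the median safely in the between-state mode. Third,
random state switching can leave a state unvisited in a short recording,
re-creating the same pathology; the cyclic progression avoids it.

## Sleep scoring

Signals are cut into 30-s epochs starting every 15 s. Rule labels use
within-recording percentiles over all epochs: wake if EMG broadband
(30–300 Hz) power exceeds its 80th percentile or the epoch contains
movement; otherwise REM if the theta/delta (6–12 over 1–4 Hz) ratio
exceeds its 70th percentile with EMG below the 25th percentile; otherwise
NREM if delta power exceeds its 70th percentile with EMG below the
median; otherwise uncertain. The precedence wake > REM > NREM resolves
the conflict cases the original rule list leaves open — movement is
physically overriding, and an epoch satisfying both sleep tests goes to
REM by its stricter EMG requirement.

A k-NN (k = 20, distance weights, 20-quantile uniform transform) trained
on the rule-labeled epochs predicts the uncertain ones; only predictions
with class probability above 0.99 are kept, and rule labels are never
overwritten. The pupil/eyelid classifier quantile-transforms six features
(max/min/SD of pupil diameter, pupil area, pupil motion, eyelid distance)
with the quantile count and k chosen from {50, 100, 500} × {5, 10} by
4-fold cross-validated macro F1 (uniform weights), reporting per-class
accuracy over repeated stratified 75/25 splits plus the summed confusion
matrix. Because the quantile transform is rank-based, disjoint class
supports still become adjacent rank blocks, so per-class accuracy
saturates slightly below 1 even at arbitrarily large separation; the
tests assert ≥ 95%.

Pupil cleaning linearly interpolates samples with tracking certainty
below 0.5, then replaces samples below the moving median minus 3 moving
MADs (30-s window) — the blink rule. Moving statistics use
`ndimage.median_filter` with reflect padding (replicate padding collapses
the edge MAD toward a single deviation value and floods the edges with
false blink flags); the moving MAD is the median filter of absolute
deviations from the moving median. With Gaussian measurement noise the
3-MAD rule intrinsically trims ~2% of the lower noise tail in addition to
true blinks.

## Spine dynamics

On spine × session presence tables: turnover_t = (gained_t + lost_t) /
present_t for each session t ≥ 2, with present_t the count at session t
(including that session's gains; a mean-of-adjacent-sessions denominator
is available, since the original denominator convention is unstated);
survival is the percentage of first-session spines still present, with a
spine leaving the survivor set permanently on its first absence (a
reappearing protrusion is a new spine under the upstream 0.5-μm
neck-shift rule); density is present spines per μm of dendrite. Integer
conservation turnover_t·present_t = gained_t + lost_t holds exactly.

## Synthetic data: what it does and does not establish

Every generator is deterministic per seed and emits objects that validate
against the package's containers unmodified.

- **LFP**: summed sinusoids over a 1/f^β background produced by exact
  spectral shaping of white noise (FFT filter), plus white noise. No
  non-stationarity, no line noise, no electrode artifacts.
- **Spikes**: a common-parent construction — a mother Poisson train
  shared with probability c plus an independent Poisson complement, both
  carrying an optional shared sinusoidal rate modulation; `rate_scale`
  thins the overall rate. This makes rate and coupling independently
  controllable, and at c = 1 with zero jitter the trains are literal
  duplicates (a latent-rate model cannot produce that limit, which is why
  spike-level sharing was chosen). No refractoriness, bursting, or
  cell-type structure.
- **Calcium**: spikes convolved with amp·exp(−t/τ), plus a shared
  neuropil background (noise smoothed to a ~0.2-s correlation time,
  positive-going) entering F with weight 0.7, plus white noise. SNR 10
  means amp/noise SD = 400/40. No photobleaching, drift, or saturating
  indicator dynamics. Recovery scenarios use minimum-gap spike trains so
  every transient is resolvable — real trains lose ~10% of events to the
  10-frame distance rule at 0.3 Hz, which is a property of the detection
  parameters, not an implementation error.
- **ROI maps**: non-overlapping 5-μm-radius disks, kept inside the
  central ~75% of a 200-μm field so border truncation in alignment
  scoring never clips genuine signal. Centroid jitter is uniform within a
  disk of the stated radius — a bounded displacement — so the
  1-μm-jitter matching checks are deterministic properties of the
  conditions rather than tail events. Replacement ROIs are placed > 8 μm
  from every live centroid, so they can never be false matches. Real ROI
  shapes, partial overlaps and segmentation noise are absent.
- **Epoch features**: class-conditional Gaussians in log-feature space
  with separation a multiple of the within-class SD, a movement flag cut
  from a latent motion feature, and derived pupil features; an option
  collapses REM pupil features onto NREM to reproduce the hard-REM
  scenario. The class-mean geometry (delta highest in NREM, ratio highest
  in REM, EMG ordered REM < NREM < wake, movement only in wake) is chosen
  so that at high separation the percentile rules recover the generating
  class exactly on every epoch they label.
- **Spines**: per-spine survival chains (loss probability per step,
  permanent once lost) with binomial gains appended as new rows; survival
  therefore decays geometrically and turnover has a closed-form
  expectation.

Passing on these conditions demonstrates the *correctness of the
computations and rules*, and the *internal consistency* of the pipeline
— not that the biological effect sizes would be recovered from real
recordings, whose noise structure is far richer.

## Problem sizes

Default test and acceptance problem sizes are chosen to make every check
statistically decisive at desk scale: 100 random pairs for STTC oracle
equivalence, 50 seeds for rate insensitivity, 100 random signals for
active-period agreement, 20 seeds per β for slope recovery (15-min
signals), 100 ROIs for calcium recovery, 20 seeds for ROI matching, 10
seed pairs for the fragmentation direction (40 neurons × 300 frames at
10 Hz), 20 draws for planted-partition recovery, 400 epochs for sleep
scoring, and 10,000 spines for survival decay.
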