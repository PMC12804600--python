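# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Coordinate frames, clocks and conventions

Maze coordinates are in cm with the origin at the maze centroid, y-up; the
three 30-cm arms radiate at 150° (arm 1), 30° (arm 2) and 270° (arm 3, the
empty/start arm) from a hexagonal hub (circumradius 4 cm, arm half-width
3 cm). Reward zones are the distal 6 cm of arms 1 and 2, with the spout
1 cm from the arm end. The 5-zone variant used by the zone decoder is
{reward1, arm1 proximal, hub ∪ arm3, arm2 proximal, reward2} with 10-cm
reward zones, chosen so the five zones tile the full footprint along the
navigation corridor; the maze never defines it otherwise.

Behavior (19 frames/s in the maze, 10 in the open field) is aligned to the
neural clock (10 Hz) by linear interpolation of the smoothed centroid at the
neural timestamps; events snap to the nearest neural frame with exact ties
going to the earlier frame. Frames are 0-based and intervals half-open
[start, end). Alignment is idempotent and preserves samples whose
timestamps coincide with neural frames. Missing coordinates spanning at
most 3 frames are linearly interpolated; longer gaps stay invalid and are
excluded from every statistic; files with more than 20% unrecoverable
frames are rejected.

## Kinematics

* **Smoothing** — centered 0.5-s moving average per coordinate, truncated
  at the edges.
* **Speed / acceleration** — speed is the frame-to-frame displacement over
  the frame interval; acceleration is the *signed* first difference of
  speed (linear acceleration), not the magnitude of the 2-D acceleration
  vector. The sign matters: the tuning analysis excludes decelerations,
  which is only meaningful for a signed quantity.
* **Tortuosity** — T(t) = L(t)/D(t) over a symmetric ±1.25-s window, where
  L sums frame-to-frame displacements and D is the distance between the
  window endpoints. Frames whose chord D falls below 0.1 cm (out-and-back
  motion) are undefined rather than capped. The session summary is the 75th
  percentile of T over frames faster than a running threshold; the
  threshold itself is the mean of per-session 75th-percentile speeds over a
  caller-supplied reference cohort (`running_speed_threshold`), since no
  reference recordings ship with the package.
* **Turn angle** — unsigned angle in [0°, 180°] between the displacement
  vectors of three consecutive frames; steps under 0.05 cm are excluded so
  centroid jitter does not dominate; histogram bins default to 30° and are
  configurable. Turn angles are invariant under rigid motions of the
  trajectory (property-tested).
* **Immobility** — maximal runs of speed < 2 cm/s lasting ≥ 1 s.
* **Open field** — 40×40 cm arena, central 20×20 cm "center" zone (half
  the linear dimension; the convention is ours), first 30 s discarded as
  adaption.

## Navigation trials

A trial is one traversal between the two reward arms: it starts at the
first frame after the previous water delivery at which speed stays at or
above 2 cm/s for 0.5 s while the animal is in the origin arm, and ends at
the first frame inside the destination reward zone — strictly before that
traversal's water delivery. Trials that spend more than 20% of their frames
in arm 3 or last over 60 s are kept but flagged unqualified (both
thresholds configurable; the qualification rule is ours). Phases partition
trial frames by region: starting = origin arm, central = hub, terminal =
destination arm; hub-excursion frames inside a trial that fall in arm 3 are
phase-'none'.

## Tuning classification

Acceleration frames are binned low = [5, 25) cm/s² and high =
[25, 50] cm/s²; negative, sub-5 and above-50 values are excluded. The
half-open low/high boundary keeps the continuum covered between the two
printed integer bins.

Significance is a circular time-shift permutation test: the observed
statistic is compared with its distribution when the trace is circularly
shifted relative to the fixed labels (uniform shifts of at least 5 s,
default 1,000 draws; one-sided p = (1 + #{null ≥ obs}) / (1 + n)). Shifts
preserve the trace's autocorrelation, so the test is exactly calibrated for
stationary traces — verified on thousands of untuned synthetic neurons.
Internally the statistic is evaluated for *every* shift at once via FFT
circular cross-correlation and the permutation draws index into that
table, which makes the batch test fast without changing its distribution.
A frame-wise one-sided Mann–Whitney U backend is available as an
alternative and is recorded in the result metadata.

Two structural problems shape the statistics:

1. **Path phases are unions of regions** (starting ≡ origin arm, central ≡
   hub), so a plain condition-vs-rest mean statistic flags every position
   cell as path-tuned and vice versa. The default statistics are therefore
   *balanced contrasts*: arm conditions contrast arm 1 against arm 2 within
   direction strata (plus a non-trial stratum), so path cells — symmetric
   across directions — cancel; phase conditions contrast the origin
   against the destination phase within the same arm, so position cells
   cancel; the center region and the central phase, which coincide inside
   trials, are separated using non-trial hub frames (center vs non-trial
   arms, and in-trial central vs non-trial hub). Strata need at least 20
   frames per side; conditions with no usable stratum are skipped and the
   neuron's flag for that modality is reported as missing, not False.
2. **Calcium kinetics lag behavior.** A transient raised in one region
   decays into the next, which biases boundary-sensitive contrasts. Tests
   therefore run on approximately deconvolved activity by default: the
   AR(1) inverse d[t] = f[t] − exp(−Δt/τ)·f[t−1] with τ = 0.4 s
   (GCaMP6f-like; configurable, disable with `deconvolve_tau=None`).

A neuron is flagged for a modality when the *minimum* p over that
modality's conditions is below α = 0.05 — the raw "one or more conditions"
rule, with no multiple-testing correction. Per-condition p-values are
exactly calibrated, but the flag-level false-positive rate is consequently
≈ 0.10 (two conditions) to ≈ 0.16 (three), and flag counts on a population
are inflated accordingly; this is inherent to the rule, not a defect, and
the per-condition p-values are all exported for stricter downstream
control. Conjunctive flags are the conjunction of the acceleration flag
with the position (or path) flag.

## Dissociation analyses

* **d′** — within each matched spatial region, frames are split by
  acceleration bin and d′ = (μ_high − μ_low)/√(0.5(σ²_high + σ²_low)) with
  unbiased (n−1) variances, computed frame-wise by default (a per-trial-mean
  backend exists); regions with under 20 frames in either group are skipped.
  Zero pooled variance yields 0 for equal means and a signed infinite
  sentinel otherwise. d′ is antisymmetric in the groups and invariant under
  common affine rescaling of the trace. Matched regions are computed per
  region and reported per region (arm 1 and arm 2 by default).
* **Encoding GLM** — x(t) = β0 + β1·Position(t) + β2·Acceleration(t) + ε,
  fit by OLS with intercept. The scalar regressors are z-scored means of
  the flagged populations' traces (the mapping from neuron sets to
  regressors is ours and is recorded in the fit metadata). Designs with
  condition number above 1e8 are rejected.
* **Ablation** — remove-and-retrain: the neuron subset is dropped *before*
  dimensionality reduction and the decoder retrained from scratch, with a
  size-matched random-removal control per seed; input-zeroing is not
  meaningful once PCA mixes channels.
* **Lick-frame control** — frames within ±0.5 s of any lick are removed.
  Both decoders share, per seed, one window split in which the validation
  windows are lick-free and the two training sets are size-matched (the
  with-lick set samples from lick and lick-free windows alike). Without
  this pairing the comparison confounds lick content with evaluation-set
  composition and training-set size, which dominate at desk scale.

## Decoders

All four models run on a small in-repo numpy reverse-mode autodiff engine
(`navscope._nn`; broadcasting ops, batched matmul, fused softmax,
attention, LSTM, temporal convolution, Adam/AdamW, cosine and plateau
schedules), gradient-checked against finite differences. Training is
bit-reproducible given (data, split seed, training seed).

* **Path transformer** — trials are projected onto the top 256 principal
  components (basis fit on training trials only), zero-padded to 196
  tokens with an attention mask (longer trials are truncated
  head-preserving, with a warning), linearly embedded to 128 dims with
  learned position embeddings and a prepended [CLS] token, passed through
  a 2-layer / 4-head / feed-forward-256 post-norm encoder (these three
  depths are ours — they are not printed anywhere — and configurable),
  and classified from the [CLS] output by a dropout-regularized MLP.
  Training: stratified 8:2 trial-level split, AdamW (lr 1e-4, weight decay
  1e-4), cosine annealing, 30 epochs, batch 16, dropout 0.3, cross-entropy.
* **Position classifier** — non-overlapping 2-s windows with a step of
  twice the window length; the label is the region at the window's final
  frame; linear embedding + layer norm → temporal convolution → biLSTM →
  final-timestep readout. Stratified 70:30 window split; Adam (1e-3, weight
  decay 1e-5), plateau-halving schedule, 50 epochs, batch 16.
* **Future-trajectory regressor** — 15 input frames → 10 outputs (5 future
  (x, y) frames), biLSTM, mean-squared-error loss (no loss is printed for
  this model; MSE is the natural choice), targets z-scored with training
  statistics and un-scaled at prediction; 80:20 split, batch 64, lr 5e-4,
  80 epochs. RMSE per axis is reported alongside the
  predict-the-training-mean baseline.
* **Zone classifier** — 10-frame windows labeled with the modal zone
  within the window (the rule for mixed windows is ours; ties break
  lexicographically), same training recipe as the regressor.

Normalization statistics, the PCA basis and the schedulers depend only on
training data (leakage-tested). "Validation" and "test" denote the single
held-out split each report is computed on.

## Synthetic sessions

The generator is kinematic, not agent-based: traversals follow arm
centerlines through the hub with trapezoidal speed profiles (per-traversal
departure/arrival accelerations drawn from 8–45 cm/s², peak speed
~22 cm/s), dwell-and-lick bouts at the spouts (first lick at a newly
visited spout is rewarded, repeats are dry), occasional arm-3 excursions
with a brief hub pause (15% of traversals by default) that provide
non-trial hub occupancy, and small centroid jitter. Traces are Poisson
event counts at rate baseline·(1 + gain·indicator), convolved with a causal
exponential kernel (τ = 0.4 s default) plus white Gaussian noise
(σ = 0.05 ΔF/F). Conjunctive neurons multiply two indicators and are
planted only on combinations that actually co-occur (the hub is crossed at
near-zero acceleration, so acceleration × center conjunctions are never
sampled). Neuron image-plane centroids are uniform — salt-and-pepper by
construction.

Default session conditions: 600 s, 500 neurons (20 position, 20 path, 40
acceleration, 5 + 5 conjunctive, 410 untuned), gain 6, baseline 0.2
events/s. The gain was set by a power analysis of the rarest planted
condition (a conjunctive cell's component contrasts sit near z ≈ 2 at gain
3 and ≈ 4 at gain 6); pure-class recovery saturates well below it. The
high-SNR decoder scenario (`high_snr_decoding_config`) uses 1200 s, 200
neurons with 5-zone position coding plus dedicated empty-arm cells, gain 8,
faster kinetics (τ = 0.25 s), higher event rate and longer dwells, so that
decoder failures indicate implementation defects rather than weak signal.

What the generator does **not** emulate: photon shot noise and motion
artifacts, slow drift and bleaching, behavioral idiosyncrasies (grooming,
rearing, variable paths within an arm), inter-neuron correlations beyond
shared behavior, and reorientation/turnaround events (which the study
annotated manually; automated detection is out of scope). Passing recovery
tests therefore shows the *analysis* is correct and calibrated under the
stated forward model — not that real cortical data would yield the same
rates.

## Validation problem sizes

The validation experiments (`navscope.experiments`, exercised by the test
suite and `scripts/acceptance.py`) use: closed-form tortuosity checks at
100 Hz; d′ convergence at 10,000 frames per group; GLM recovery with 200
Monte-Carlo seeds at n = 5,000; calibration on 3,000 untuned neurons with
4,999 permutation draws (the FFT path makes draws nearly free); planted
recovery over 10 default sessions; decoder signal over 3 high-SNR sessions
and shuffled-label nulls over 5 re-shuffles, with reduced architecture
dims (32 components / 64 tokens for the transformer, 24–32 hidden units
for the recurrent models); lick control and ablation over 5 paired seeds.
The GLM bias check uses a per-coefficient 3-SE band plus a joint
chi-square test at the 1% level, the correctly sized version of a
per-coefficient 2-SE rule applied to three coefficients at once.

## Known limitations

* The path/position dissociation is only identifiable where the paradigm
  provides counterbalanced coverage; the central-phase/center-region pair
  is separable only through non-trial hub occupancy, and sessions without
  it will report those conditions as untestable.
* Flag-level false-positive rates inherit the uncorrected one-or-more rule
  (see above); population *counts* of tuned cells are upward-biased by
  design.
* The AR(1) deconvolution assumes a single known decay constant; real
  indicators vary per neuron.
* The decoders are desk-scale: they establish correctness and
  chance-vs-signal separation, not state-of-the-art decoding accuracy.
* The trajectory generator's stereotypy makes direction decoding easier
  than in real sessions with variable paths.
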