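# Methods

This note documents the models, parameter choices, and numerical
decisions behind `emgmotion`, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and conditioning

Recordings are `samples × channels` matrices in microvolts at a nominal
1 kHz sampling rate: eight motion muscles (trapezius, pectoralis major,
posterior/middle/anterior deltoid, triceps, brachioradialis, biceps) plus
a ninth wrist-flexor channel reserved for the emergency-stop clench.
`Recording.estop_channel` is explicit (`None` when absent); the synthetic
generator and the CLI bind it to index 8 rather than assuming every
recording has nine channels.

Conditioning applies five stages in order: per-channel mean removal, a
Butterworth band-pass, a 50 Hz notch, full-wave rectification, and
amplitude normalization.

- **Band edges 20–450 Hz.** Surface EMG carries most of its power between
  ~20 and ~450 Hz; the nominal 500 Hz upper edge of the EMG band equals
  the Nyquist frequency at 1 kHz sampling and is unrealizable, so the
  default upper cutoff is 0.9 × Nyquist. A cutoff at or above Nyquist
  raises a configuration error naming the constraint.
- **Filter order.** `FilterSpec.order` (default 4, must be even) is the
  true order of the realized band-pass (two second-order sections), not
  the per-band design order.
- **Zero-phase by default.** Offline forward–backward filtering doubles
  the effective magnitude response and, more importantly, introduces no
  group delay, so detected activity onsets are not shifted against the
  raw signal. `zero_phase=False` gives a causal variant for
  streaming-style use.
- **Notch.** A second-order IIR notch with Q = 30 (≥ 30 dB at 50 Hz,
  ≤ 1 dB at 100 Hz). A Butterworth band-stop of ±1 Hz is available as
  `notch_design="bandstop"` for users who want every filter in the chain
  to be Butterworth.
- **Normalization mode.** `normalize_amplitude` offers per-channel peak
  normalization (each channel's maximum maps to 1, the usual single-channel
  convention and the function's default) and global-peak normalization
  (all channels divided by the recording's single maximum). The
  recognition pipeline uses the **global** mode: per-trial per-channel
  peak normalization maps every channel's burst to roughly the same
  normalized RMS (≈ 1 / crest factor) *regardless of how strongly that
  muscle participated*, which erases the inter-channel activation pattern
  that distinguishes the motions; global normalization removes
  inter-trial gain while preserving that pattern. Note that global
  normalization is the one stage that couples channels; all filtering
  stages remain strictly channel-wise. MVC-referenced normalization would
  be preferable when calibration contractions are available, but requires
  data this pipeline does not assume.

## Sample-entropy segmentation

The eight motion channels of the conditioned recording are summed and
SampEn(m, r) = −ln(A/B) is computed over sliding windows, where B counts
ordered pairs of distinct length-m templates within Chebyshev distance r
and A the corresponding length-(m+1) counts, self-matches excluded, with
T = L − m templates at both lengths. Defaults: m = 2, r = 0.25 σ,
activity threshold d = 0.6 (ties active), 128-sample windows stepped by
64 — deliberately the same geometry as the feature frames so entropy
windows and feature windows align index-for-index.

Numerical decisions:

- **Tolerance scale.** σ is the standard deviation of the *whole* summed
  signal, not of each window. A motion burst dominates σ, so rest windows
  fluctuate far below r and read as regular (SampEn ≈ 0) while burst
  windows fluctuate at the scale of r and read as irregular — this
  amplitude-to-regularity coupling is what makes a fixed threshold d
  workable. Per-window σ would collapse r during rest and destabilize
  the threshold.
- **Finite cap.** When no template pair matches at either length the
  statistic is capped at ln(T(T−1)), the largest finite value −ln(A/B)
  can attain; this keeps thresholding total and profiles serializable.
- **Degenerate rest-only recordings.** Because r scales with the signal's
  own σ, SampEn is invariant under rescaling — and therefore cannot, by
  itself, notice that a recording contains *no* activity at all (its
  noise still fluctuates at the scale of its own σ and would read as
  uniformly active). `sampen_profile` guards this case with a
  scale-invariant contrast check: if the peak sliding-window RMS is less
  than `contrast_min` (default 4) times the `baseline_quantile` (default
  10th percentile) window RMS, the recording has no amplitude contrast to
  segment and the tolerance is widened to the full signal range, making
  the profile read uniformly regular. Stationary noise keeps this ratio
  near 2; genuine bursts push it above 10 on the synthetic benchmark, so
  the floor of 4 separates the regimes with a margin on both sides. Being
  a ratio of RMS values, the guard preserves scale invariance of the
  profile.
- **Segment post-processing.** Active runs are mapped to sample intervals
  `[first_window_start, last_window_start + window_len)`; gaps shorter
  than `merge_gap_s` (0.2 s) are merged and segments shorter than
  `min_segment_s` (0.3 s) dropped, suppressing one-window flicker. Both
  rules can be disabled by passing 0.

## Features

Frames of 128 ms with 64 ms step are tapered (symmetric Hanning window by
default, rectangular available) and reduced per channel to RMS,
population variance (1/N), MAV, SSI (sum of squares), and waveform
length — 40 columns over eight channels, channel-major order. The taper
is applied before all features for consistency with the framing
convention even though time-domain features do not require it. A lag-4
normalized autocorrelation (AC4) is implemented but excluded from the
default set, keeping the 40-column layout; it returns 0 for zero-variance
frames, where the ratio is undefined.

## Classifier and tuning

A soft-margin SVM with RBF kernel κ(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖²/2δ²) is
parameterized internally by scikit-learn's γ = 1/(2δ²); exact conversion
helpers are exposed and both (C, γ) and (C, δ) are accepted at the CLI.
Multiclass uses one-vs-one voting, the standard SVM reduction. Feature
columns are z-scored with statistics from the training fold only (RBF
distances need comparable scales); `scale=False` preserves the raw
pipeline. Training windows are those lying fully inside detected active
segments, labeled with their trial's motion label; rest windows are
excluded by default.

The (C, δ) search is a small real-coded genetic algorithm on (log₁₀ C,
log₁₀ δ): tournament selection (k = 3), BLX blend crossover (rate 0.8),
per-gene Gaussian mutation (rate 0.1, σ = 0.25 log units), elitism 1,
default ranges C ∈ [10⁻³, 10³] and δ ∈ [10⁻², 10⁴]. Fitness is mean
stratified k-fold accuracy on folds drawn once per run, so all candidates
are compared on identical splits. The conventional default (C = 1,
γ = 1/num_features) is seeded into the initial population as a warm
start; combined with elitism this guarantees the tuned result never
scores below the default on those folds, and the best-fitness curve is
non-decreasing by construction. Fitness evaluations are memoized on
rounded genomes.

Evaluation follows the repeated-cross-validation convention: stratified
5-fold, re-randomized per repeat, with overall and per-class accuracy
reported as mean ± sd across repeats, plus a pooled confusion matrix and
per-class precision/recall/F1 (zero-denominator cases yield 0 with a
note).

## Action decisions and the safety stop

Window predictions inside a detected segment are majority-voted into one
action label with confidence = winning share. Ties break by the larger
summed per-class decision value over the segment's windows, then by model
class order — deterministic by construction. A recording with no active
segment yields an empty decision list rather than an error.

The emergency-stop detector band-passes the estop channel, computes a
sliding 128 ms RMS, and takes baseline statistics from the first 0.5 s of
the trace; an event fires when RMS exceeds baseline mean + 5 sd for at
least 200 ms (one event per exceedance run, timestamped at its first
sample). The detector therefore assumes a quiet initial baseline window —
a clench inside the first half second inflates the threshold instead of
firing. Exported label streams order events by time with estop rows
before motion rows at equal timestamps.

## The synthetic generator

Each channel is `drift + mains + rest_noise + envelope · synergy · gain ·
carrier`, with the carrier zero-mean unit-variance Gaussian noise
band-limited to 20–450 Hz — the standard interference-pattern surrogate
for surface EMG — and a trapezoidal envelope (15 % rise/fall) over a
scheduled burst of 1–2 s embedded in 0.5–1.5 s rest pads. Five synergy
vectors give each motion an anatomically sensible dominant-muscle
pattern (anterior deltoid + pectoralis for flexion, middle deltoid +
trapezius for abduction, pectoralis for internal rotation, posterior
deltoid for external rotation, biceps + brachioradialis for elbow
flexion); the exact weights are arbitrary but fixed, documented
constants. Amplitudes default to a 2 μV RMS rest baseline, 100 μV burst
gain, 5 μV mains and 3 μV drift — typical well-prepped surface-EMG scales,
chosen so the artifacts are present and worth filtering while the rest
baseline remains statistically stationary between the scheduled burst
window and its flanks. The label `"rest"` generates a trial with the
burst window scheduled but silent. All outputs are pure functions of
(config, label, seed); dataset child seeds derive from one seed.

What the generator does **not** emulate: motor-unit physiology and firing
statistics, fatigue-related spectral compression, electrode lift/shift,
movement artifacts below 20 Hz beyond smooth drift, crosstalk between
channels, and inter-subject variability. Consequently the synthetic
benchmark demonstrates that the pipeline's stages compose correctly and
recover the structure they assume — not that these accuracy levels
transfer to real recordings, where class overlap (e.g. internal vs
external rotation sharing muscles) makes the problem genuinely harder.
The near-perfect synthetic cross-validation scores should be read in that
light.

## Problem sizes

The shipped benchmark sizes keep a full run on one CPU to a few minutes:
100 trials (20 per class) for window-level cross-validation (≈ 2 000
windows × 40 features; 10 × 5-fold), a GA at population 10 × 10
generations with 5-fold fitness, 100 fresh single-action trials for
action-level evaluation, and 25 trials for burst-recovery and estop
checks. All sizes are parameters, not constants.

## Known limitations

- Segmentation assumes at most a handful of well-separated bursts and a
  globally dominant activity scale; recordings whose activity level
  drifts slowly across minutes would need a rolling σ.
- The contrast guard targets the all-rest degenerate case; a recording
  that is *entirely* one long contraction (no rest at all) would likewise
  show low contrast and be read as unsegmentable.
- The estop detector's baseline must be clench-free; in deployment the
  baseline would be calibrated once at session start rather than per
  recording.
- Per-window evaluation treats windows as exchangeable; windows from the
  same trial are correlated, so fold assignment by window (not by trial)
  gives optimistic window-level estimates on small trial counts. The
  action-level evaluation on fresh trials does not share this bias.
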