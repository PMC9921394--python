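# Methods

This note records the models, parameter choices and numerical conventions
behind `reptrack`, and what the synthetic evaluation does and does not
demonstrate.

## Problem setting

A person performs a *protocol*: an ordered sequence of exercise series
(dips, pull-ups, squats), each of several repetitions, separated by breaks.
Two body-worn inertial sensors (chest, hand) deliver three acceleration
axes each at 30 Hz.  The system must (a) recover the ordered exercise
sequence — the *scenario* — and (b) count the repetitions of every series.
Posture or movement-quality assessment is out of scope, as is any use of
the positioning hardware such recordings are often collected with; the
pipeline consumes only the six acceleration channels, which prior
sensor-selection work showed to be sufficient for this task.

## Signal model and preprocessing

Recordings are N×M matrices (time × channel) on a uniform grid.  Irregular
input streams are linearly interpolated onto the 30 Hz grid; multiple
sensor streams are synchronized by resampling each onto the grid spanning
the intersection of their time supports.  No extrapolation is performed
beyond the observed support — values there would be fabricated.  Segments
are half-open `[start, end)` with 0-based sample indices, so protocol
segments tile a recording unambiguously.  Units are m/s²; the raw-data
pipeline never rescales, so units only matter for interpretability.

## Window classifier

* **Input** 50 samples × 6 channels; **conv** 5 filters with a 7×1 kernel —
  7 along time, shared across channels, no padding (50−7+1 = 44), ReLU;
  **pool** max over 2×1 time pairs (44→22); **flatten** 22·6·5 = 660;
  **dense** softmax to 4 classes.  Parameters: 5·(7+1) + 4·(660+1) = 2684,
  asserted at build time.
* **Soft labels.**  A training window's target is the fraction of its
  samples in each class.  Because every break is at least 63 samples and a
  window is 50, a window can mix at most one exercise with break samples.
* **Hard-label rule.**  For scoring, a window counts as an exercise when
  its exercise mass exceeds 1/(2·50) = 0.01, even if break holds the
  majority; among exercises the largest mass wins, ties resolved by class
  index.  The threshold makes the rule well defined for softmax outputs,
  which are never exactly zero; exact class-fraction targets are unaffected
  since their nonzero exercise mass is at least 1/50.
* **Training.**  Categorical cross-entropy against the soft targets,
  Adam (learning rate 1e-3, batch 64), at most 200 epochs with early
  stopping on validation loss (patience 10) and best-weights restore.
  Datasets are split 70:15:15 into train/validation/test at window level;
  normalized variants z-score each channel with statistics fitted on the
  training split only.  The network is small enough that the forward pass,
  backprop and the optimizer are implemented directly on numpy arrays; an
  independent loop-based forward oracle in the test suite guards the
  vectorized implementation.
* **Training regimes.**  Windows are sliced with step 50 (non-overlapping,
  homogeneous-dominated) or step 25 (overlapping, includes heterogeneous
  boundary windows).  The benchmark uses the overlapping-window raw-data
  variant, the configuration chosen for deployment; all four
  regime × normalization variants are constructible through the same API.

## Streaming and post-processing

Streaming inference slides the window one sample at a time; row *t* of the
probability stream is the window covering samples `[t, t+50)` and is
assigned to sample `t+49` — the causal choice for live operation (the first
49 samples inherit row 0).  Each class stream is then

1. smoothed with a **forward** moving average of w = 50 samples (the tail
   averages over the remaining samples only);
2. binarized at 0.5 (≥ convention);
3. cleaned by run-length filtering: 1-runs of length ≤ δ₁ = 90 are removed
   *first*, then 0-runs of length ≤ δ₀ = 60 are filled.  Comparisons are
   strict (a run of exactly δ samples is removed/filled); both operations
   are idempotent.

The causal alignment and the forward moving average deliberately cancel:
for an idealized classifier whose window output equals the window's true
class fraction, the binarized stream switches exactly at the true segment
boundaries (the ~25-sample anticipation of the forward average offsets the
~25-sample latency of causal assignment).  Gap-filling runs last so that a
just-cleaned activity block cannot be re-fragmented.

Streams are processed per class and can therefore conflict.  The per-sample
winner is the single active exercise stream; break when none is active;
with several active, the stream active for the longest contiguous stretch
up to that sample (ties by class index).  Winners compress into segments;
the scenario is the ordered non-break label sequence.

δ₁ and δ₀ sit just below the corpus minima (shortest exercise occurrence
91 samples, shortest break 63): real activities and breaks survive, while
shorter activations/dropouts are treated as noise.

## Repetition counting

Per activity, only the channels that carry the movement are used — dips:
chest-z, hand-x, hand-z; pull-ups: chest-y, chest-z, hand-z; squats:
chest-z.  Each channel slice is filtered with a zero-phase
(forward–backward) order-2 Butterworth low-pass; normalized cutoffs
(fraction of Nyquist) are 0.05 (dips), 0.04 (pull-ups), 0.06 (squats),
i.e. 0.75/0.6/0.9 Hz at 30 Hz — above the fundamental of the slowest
plausible repetition but far below noise.  Zero-phase filtering avoids
displacing peaks near segment edges, which matters because recognized
segments can be slightly shifted.  Repetitions are counted with
minimum-distance peak detection (40/50/30 samples, just below the minimum
per-repetition durations) plus a prominence floor of 10 % of the segment's
signal range, which suppresses ripple on near-flat channels (set it to 0
for pure distance-based counting).  Because a repetition may be an upward
or a downward excursion depending on channel and exercise, each channel is
counted with automatic polarity — max(peaks of x, peaks of −x); with one
dominant excursion per repetition the minority polarity sees one fewer
extremum, so the maximum is the cycle count.  Per-channel counts are
averaged and rounded half-up.  Counting on a segment uses the segment
slice only (no context padding).

## Synthetic generator

The generator emulates the protocol statistics of the corpus the method was
designed around:

* scenario drawn from the 15-type mix with its protocol frequencies
  (e.g. pull-ups/dips/squats has weight 28 of 78);
* repetition counts uniform in the per-activity ranges (dips 2–12,
  pull-ups 1–14, squats 2–15);
* per-repetition durations uniform in the per-activity ranges (dips 48–171,
  pull-ups 55–220, squats 33–130 samples), then rescaled (and clipped back
  into those ranges) so the series total lands in the per-activity
  occurrence range (dips 135–768, pull-ups 91–765, squats 157–956).  The
  per-repetition bounds are the hard constraint; the occurrence maximum is
  relaxed when infeasible (14 pull-ups × 55 samples > 765).  Without the
  occurrence floor, a single short pull-up could be shorter than δ₁ and no
  segmentation — however perfect — could retain it; the corpus the
  thresholds were derived from contains no such occurrence, so the
  generator does not either;
* breaks uniform in 63–1844 samples, bracketing the protocol on both ends
  so edge cases are exercised;
* each repetition is one half-cosine excursion-and-return on the
  activity's informative channels — visually similar to real repetition
  bursts while analytically countable (exactly one dominant extremum per
  repetition).  Default amplitudes: 3.0 m/s² informative, 1.0 m/s² on the
  other channels during exercise, over a 9.81 m/s² gravity baseline on the
  z channels, with Gaussian noise (sd 0.3 m/s²) everywhere and sparse
  half-cosine transients during breaks (0.05 events/s, ~1 m/s², 20
  samples) emulating incidental movement.  Amplitudes and noise are stated
  assumptions — the study published no signal model — and are chosen to
  give a workable signal-to-noise ratio for both raw and normalized
  pipelines.

What the generator does **not** model: person-specific style and fatigue,
amplitude drift within a series, sensor orientation changes, correlated
(non-white) noise, and any correlation between repetition count and tempo
beyond the occurrence-range constraint.  Synthetic results therefore
demonstrate that the pipeline's logic is sound under the corpus's timing
statistics, not that the accuracy figures transfer to real recordings.

## Benchmark sizes and determinism

The standard benchmark trains on 40 generated protocols (≈8,000
overlapping windows — comparable to the corpus the classifier regime was
designed for) and evaluates on a disjoint 100-protocol corpus; the
noise-free diagnostic uses 15/15.  These sizes give stable estimates while
keeping a full run in the minutes range on one CPU.  All randomness
(corpus draws, splits, weight initialization, batch order) derives from a
single seed via independent substreams.  On the noise-free corpus the
pipeline is expected to be exact — scenario accuracy 1.0 and every
repetition count correct — which localizes any regression to
windowing/post-processing/counting logic rather than to noise robustness.

## Known limitations

* The moving-average/alignment cancellation is exact only for an idealized
  soft classifier; real boundary jitter of a few samples remains, so an
  occurrence within a couple of samples of δ₁ can occasionally be lost.
* The conflict rule for simultaneously active streams is a design choice;
  the corpus statistics make conflicts rare, so it is weakly exercised.
* `activity_sample_accuracy` is per-sample recall against ground truth;
  held-out *window* accuracy is a different quantity (reported separately)
  and the two are not comparable.
* Repetition evaluation pairs recognized segments to ground-truth segments
  by maximal same-label overlap (split segments sum; missed segments score
  zero; spurious segments enter with truth 0).  Other pairings are
  defensible; this one never rewards a missed or mislabelled series.
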