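# Methods

This note documents the models, numerical choices and defaults behind
`bcgsleep`, and what the synthetic-data generator does and does not
emulate.

## Signal model and preprocessing

A bed-leg BCG recording is four load-sensor channels (S1..S4) sampled
uniformly at a nominal 200 Hz, optionally with a synchronized reference
pulse channel. The heartbeat appears as a short oscillatory wavelet per
beat riding on a large respiration baseline; the four channels carry the
same wavelet with different gains and small relative delays.

Preprocessing is a Butterworth band-pass with edges 1 and 8.5 Hz followed
by min-max normalization to [−0.5, 0.5]:

* **Filter order and phase.** Order 2, applied forward and backward
  (`sosfiltfilt`), so the effective magnitude response is the squared
  Butterworth response and the phase is exactly zero. Zero phase was chosen
  because beat *timing* is the quantity of interest downstream: a causal
  filter would shift every detected beat by its group delay, and a
  frequency-dependent delay would distort RR intervals.
* **Normalization scope.** Min-max over the full analysis signal passed in;
  callers that want per-window normalization can window first. A constant
  signal maps to all zeros rather than raising, so a dead channel does not
  abort a batch run.
* **Channel combination.** `s1`, `s2`, `mean_s1_s2`, `mean_all`. The
  samplewise mean of S1 and S2 is the default in the CLI; averaging all
  four channels degrades detection because of inter-sensor phase shifts
  (the simulator reproduces this via per-channel delays).

## Beat detection

* **Peak candidates.** A sample is a local-maximum candidate when it is
  strictly greater than its left neighbour and at least as large as its
  right neighbour (plateaus yield their leftmost sample). Array endpoints
  are candidates only when they dominate their one-sided refractory
  window: an edge sample that is merely rising toward an unseen maximum
  beyond the recording is not a peak.
* **Refractory conflict resolution.** Candidates closer than the 0.7 s
  refractory are resolved greedily by descending amplitude with ties
  broken toward the earlier index — deterministic and order-independent.
  The 0.7 s spacing bounds the detectable heart rate at ~85 bpm, which is
  appropriate for sleeping adults and suppresses double-detections on
  multi-lobed BCG wavelets. The same refractory is used for template
  seeding and for final beat picking.
* **Template.** 0.8 s span (±0.4 s around the peak), samplewise mean of
  all usable segments; segments whose window overruns the signal are
  skipped. The library supports both a per-recording self-template (CLI
  default) and a pooled template built from training recordings and
  applied to held-out data; tests verify the pooled template generalizes.
* **Sliding correlation.** Pearson correlation between the template and
  the equal-length window centred at every sample. Positions whose window
  overruns either end are assigned 0 (a partial window would bias the
  correlation), as are zero-variance windows. The implementation uses
  O(nL) moving sums, which agrees with a per-window Pearson oracle to
  better than 1e-9; cumulative-sum differencing was rejected as too lossy.
  The trace is divided by 2 (mapping r ∈ [−1, 1] to [−0.5, 0.5]) and
  negatives are zeroed — only positive correlation indicates a beat.
  Per-recording min-max scaling of the trace was rejected because it would
  make traces non-comparable across recordings.
* Beats are refractory-constrained maxima of the rectified trace; flat
  zero stretches are never beats. RR intervals are first differences,
  timestamped at the closing beat.

## Agreement metrics

* **Pairing.** The published criterion classifies each estimated interval
  against "the correct answer" without specifying the pairing; this
  package pairs one-to-one by nearest timestamp, assigned greedily in
  ascending order of time gap, and leaves a candidate unmatched when its
  gap exceeds half the local reference RR (it is then closer to a
  different beat than the one it would be scored against).
* **Precision vs detection rate.** Precision counts only *paired*
  intervals (correct / (correct + incorrect)); reference intervals that
  attracted no estimate are reported separately as `detection_rate`.
  Missing a beat and mistiming a beat are different failure modes and are
  reported as distinct figures.
* Bland–Altman differences are estimate − reference; limits are
  bias ± 1.96 × sample SD (ddof = 1). Lin's CCC uses biased 1/n moments,
  following the original definition. RMSE and MAE are reported in ms.
* 30-s segmentation assigns intervals to segments by timestamp; segments
  without reference coverage are excluded from per-segment reports.

## HRV features

* **Windows.** A 5-min initialization precedes epoch 1; epoch k consumes
  a buffer of 300 + k·τ seconds. VLF is computed from the trailing 300 s
  of the buffer, LF from the trailing 25 s, HF from the trailing 6 s, and
  RR mean/SD from the trailing τ seconds. For τ = 30, epoch 1: buffer
  330 s, VLF window (30, 330), LF (305, 330), HF (324, 330). The LF and HF
  windows are too short to resolve their own band edges well; they are
  implemented as stated, and a `single_window` option evaluates all bands
  on the 300-s window as a conventional sanity alternative (off by
  default). The LF/HF ratio uses the separately windowed LF and HF powers.
* **Spectra.** The FFT input is the standard HRV tachogram: the (time, RR)
  points in the window linearly interpolated onto a uniform 4 Hz grid
  (clamped beyond the first/last point) and mean-subtracted. Applying the
  FFT to the raw BCG waveform instead would conflate waveform morphology
  with rhythm. Band power is a rectangular-taper periodogram normalized so
  bin powers sum to the mean square of the tachogram (Parseval); bands are
  half-open [low, high) so adjacent bands never double-count, except that
  a band reaching Nyquist includes the Nyquist bin. The VLF low edge
  (0.0033 Hz) coincides with the first resolvable bin of a 300-s window
  (1/300 Hz), which is included.
* A single interval in a window yields SD 0 by convention; an HF power of
  exactly 0 (perfectly constant rhythm) makes LF/HF +inf, which callers
  must exclude before model fitting.

## Sleep-stage model

* **Form.** Five independent one-vs-rest logistics over (RR mean, RR SD,
  VLF, LF/HF), matching the per-stage probability form; no softmax
  normalization is applied, so the five probabilities need not sum to 1.
  Classification is argmax with ties broken in the fixed order WAKE, REM,
  N1, N2, N3.
* **Fitting.** Full-batch gradient descent on mean cross-entropy
  (the single-layer case of backpropagation), learning rate 0.1, 5000
  iterations, zero initialization — deterministic without a seed. Features
  are z-scored over the training set inside `fit_params` and the transform
  is stored with the coefficients: coefficient magnitudes of order one are
  only meaningful on standardized inputs, since raw VLF power is orders of
  magnitude smaller than mean RR in seconds. A stage absent from the
  training labels is flagged degenerate rather than raising.
* **Reference coefficients.** A published coefficient set ships with the
  package for reproducing the functional form; the feature scaling under
  which it was estimated was not published, so its predictions are
  illustrative, not calibrated. The bundled published confusion matrix is
  validated on load (stated per-stage epoch counts must equal row sums);
  its 5-stage trace/total accuracy evaluates to 87.1% and its 4-stage
  accuracy after merging N1+N2 to 88.6% — `accuracy()` always reports
  trace/total. Epochs during the 5-min initialization are not scored.
* Leave-one-subject-out evaluation fits on all other subjects and sums
  per-fold confusion counts; 4-stage accuracy merges N1 and N2 into LIGHT,
  conserving the total epoch count exactly.

## Synthetic data

`simulate_bcg` emulates exactly the structure the pipeline is sensitive
to, and nothing more:

* each beat stamps a Gaussian-windowed 7 Hz cosine (0.3 s support) into
  every channel — inside the 1–8.5 Hz passband so preprocessing preserves
  it; the shape is configurable;
* RR intervals are Gaussian (default 60 bpm mean, 5 bpm jitter, truncated
  at 0.4 s) — no long-range HRV structure;
* channels differ by gain (1.0, 0.9, 0.7, 0.6) and delay (0, 5, 12,
  18 ms), emulating inter-sensor phase shift; a 0.25 Hz respiration
  sinusoid and white noise at the configured SNR (default 10 dB, measured
  against the wavelet-train power per channel) are added;
* the reference channel is a clean impulse-like pulse train at the true
  beat times, standing in for a fingertip pulse sensor whose beat
  extraction is trivial by construction.

It does **not** model movement artifacts, posture changes, sensor drift,
nonstationary heart rate, or physiologically realistic BCG morphology
(I/J/K lobes). Passing tests on this generator therefore demonstrate the
correctness of the algorithmic chain under the stated noise model, not
clinical performance on real sleepers.

`simulate_sleep_night` inverts the staging model: stages follow a sticky
first-order Markov chain (self-transition 0.9, uniform otherwise, hence a
uniform stationary distribution — not fitted to any real hypnogram), and
features are drawn from stage-conditional Gaussians in the standardized
feature space. Each stage's mean vector is found by a small linear
program maximizing that stage's decision margin within a ±15 box (margin
capped at 8); parameters for which some stage can never win the argmax
are rejected as degenerate. With noise SD → 0 the labels are recovered
exactly by construction.

## Problem sizes and tolerances

Default test and acceptance problem sizes were chosen as the smallest
that make the statistical checks stable: 10-minute recordings for
end-to-end detection (≈600 beats), 5000 epochs for coefficient recovery
(MLE sampling error ≈ 0.05 per coefficient, so the ±0.15 check is ≈3 SE),
20 random signal/template pairs for the correlation oracle (1e-9), and
1e-12 for the closed-form statistics oracles. Gradient-descent
convergence was verified to be limited by sampling noise, not iteration
count, at the 5000-iteration default.

## Known limitations

* The detector assumes a quasi-stationary wavelet shape per recording; a
  single pooled template degrades when morphology differs strongly across
  subjects.
* The 0.7 s refractory makes heart rates above ~85 bpm undetectable by
  design; the simulator's truncation at 0.4 s RR is likewise a floor.
* The nearest-timestamp pairing can mis-pair near half-RR offsets when
  the estimate is systematically delayed by more than half a beat.
* The short LF (25 s) and HF (6 s) windows under-resolve their bands;
  the resulting powers are best treated as model inputs, not as
  physiological band-power estimates.
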