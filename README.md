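# bcgsleep

Heartbeat detection, heart-rate-variability (HRV) agreement analysis, and
logistic sleep staging for **bed-leg ballistocardiogram (BCG) sensors**.

A ballistocardiogram records the subtle whole-body recoil caused by each
cardiac ejection of blood. Load sensors placed under the four legs of an
ordinary bed pick this up without any contact with the sleeper, which makes
bed-leg BCG attractive for long-term, unobtrusive sleep monitoring — but the
signal is noisy, posture-dependent, and differs in gain and phase across the
four sensors. This package implements a robust processing chain from raw
multi-channel bed-sensor signals to beat-to-beat (RR) intervals, HRV
features, and a five-stage sleep hypnogram, together with the agreement
metrics needed to validate the chain against a reference pulse sensor and a
synthetic-data generator so every stage is testable without recorded data.

## Method

**Beat detection by template matching.** The selected channel combination
(S1, S2, their mean, or the mean of all four) is band-pass filtered
(Butterworth, 1–8.5 Hz, zero-phase) to remove the respiration baseline, then
min-max normalized to [−0.5, 0.5]. Local peaks with a 0.7 s refractory
spacing seed the template: the 0.8 s segment around each peak (±0.4 s) is
extracted and the samplewise mean of the segments is the heartbeat template.
The signal is then scanned with a sliding Pearson correlation against the
template; the trace is halved into [−0.5, 0.5] and negative values are
zeroed, and beats are the refractory-constrained local maxima of the
rectified trace. RR intervals are first differences of the beat times.

**Agreement metrics.** Estimated RR intervals are paired one-to-one with
reference intervals by nearest timestamp. With x the estimated and y the
reference interval of a pair,

- precision = correct / (correct + incorrect), where a pair is *correct*
  when |x − y| / y ≤ 10%;
- RMSE = √(Σ(yᵢ − xᵢ)²/n) and MAE = Σ|yᵢ − xᵢ|/n, in ms;
- Bland–Altman bias ± 1.96 SD limits of agreement, and Lin's concordance
  correlation coefficient CCC = 2·cov(x,y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²).

**Sleep staging.** Each stage S ∈ {WAKE, REM, N1, N2, N3} has an independent
logistic model over per-epoch HRV features

σ_S(τ) = 1 / (1 + exp(−(A + B·RR(τ) + C·RRstd(τ) + D·VLF(τ) + E·LF(τ)/HF(τ))))

where RR and RRstd are the mean and SD of the RR intervals in the τ-second
epoch (default τ = 30 s), and VLF (0.0033–0.04 Hz), LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) are band powers of the RR tachogram over trailing windows of
5 min, 25 s and 6 s respectively, after a 5-min initialization buffer. An
epoch is assigned the argmax stage. Coefficients are fitted one-vs-rest by
full-batch gradient descent on z-scored features
(`SleepStageModel(...).fit()` returns a results object with the
coefficients, the standardization, and a `summary()` table), and
leave-one-subject-out evaluation produces a combined confusion matrix with
5-stage and 4-stage (N1+N2 merged) accuracies.

## Worked example

Simulate a 10-minute night, detect beats, score agreement against the
ground-truth pulse channel, and stage the epochs:

```bash
bcgsleep simulate --out night --duration 600 --seed 7
bcgsleep detect   --input night/recording.csv --out detected
bcgsleep evaluate --est detected/beats.txt --ref night/true_beats.txt --out agreement
bcgsleep stage    --beats detected/beats.txt --out staged
```

which logs

```
INFO wrote 606 beats over 600 s to night
INFO detected 607 beats (606 RR intervals)
INFO precision 1.000  rmse 2.2 ms  mae 1.8 ms  detection 1.000
INFO scored 10 epochs
```

All 605 paired RR intervals fall within the 10% criterion (precision 1.000),
the root-mean-square timing error is 2.2 ms, and `agreement/report.csv`
additionally reports a Bland–Altman bias of −0.00001 s with limits of
agreement ±0.004 s and a Lin CCC of 0.9996 — the detector reproduces the
reference rhythm almost exactly at this 10 dB SNR. The 600 s recording
yields 10 scored epochs (5-min initialization + 10 × 30 s), written as
`staged/hypnogram.tsv`. The same steps are available as library calls
(`simulate_bcg`, `run_detection`, `evaluate_rr`, `compute_features`,
`SleepStageModel`).

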