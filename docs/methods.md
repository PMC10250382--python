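# Methods

This note documents the models, numerical choices and limitations of
`ppgbp`. It is the design record; empirical numbers quoted here are the ones
computed by the test suite and `scripts/acceptance.py`.

## 1. The oscillometric premise

External pressure applied to a finger artery modulates the amplitude of the
optical pulse: as the applied pressure P sweeps from well below diastolic to
above systolic pressure, the beat amplitude rises and falls, peaking near
mean arterial pressure (MAP). The estimation problem is to map a 40-s,
43-Hz, 9-channel PPG recording under a progressive finger press, plus the
synchronized force signal, to systolic and diastolic pressure (SBP, DBP).
MAP is defined throughout with the classical estimate MAP = DBP + PP/3
(PP = SBP − DBP).

## 2. Synthetic data generator (`ppgbp.simulate`)

Each virtual subject has SBP ~ U(95, 175) and DBP ~ U(60, 105) mmHg
(redrawn until PP ≥ 20 mmHg, since the intervals overlap), heart rate
~ U(55, 100) bpm, a finger-centre offset ~ N(0, 0.5²) in grid units, and
5 recordings with ±2 mmHg per-case BP jitter emulating repeat measurements.
The BP intervals span a typical clinical population without degenerate
cases; 5 cases/subject matches the standard repeated-measurement protocol.

A recording is

```
ppg_i(t) = baseline + A·g_i·exp(−(P(t) − MAP)² / 2σ²)·pulse(t) + drift + ε
```

* **Pressure ramp** P(t) = P_max·(t/40 s); P_max = 215 mmHg is *fixed across
  subjects* (1.2× the largest jittered SBP the generator can draw), so the
  force channel carries no per-subject label information beyond the
  oscillometric geometry itself. Cases whose SBP the ramp would not cover by
  20 % are rejected as unlearnable. Force = P / 25 mmHg·unit⁻¹, plus a small
  smooth wobble.
* **Oscillometric bell** width σ = 0.4·PP: the bell's spread scales with
  pulse pressure, which is what lets a learner recover PP (and hence
  SBP/DBP separately) rather than MAP alone.
* **Pulse template**: two Gaussians per cardiac period — systolic peak at
  0.25·T with width 0.06·T, dicrotic bump at 0.55·T at 30 % height — the
  minimal beat shape with robustly detectable peaks.
* **Channel gains** g_i = exp(−‖x_i − offset‖²/2·1.5²) over the 3×3 detector
  grid: a Gaussian illumination/placement profile. This is a modelling
  choice; no quantitative placement model is available for this sensor
  class.
* **Noise**: white noise with SD 3 (≈20 dB per-beat SNR at unit gain and
  pulse amplitude 100) and a 0.05-Hz drift of amplitude 10, below the PPG
  band-pass and so mostly removed by preprocessing.

Subject-level draws and noise use separate seeded streams, so datasets with
the same subject seed but different noise seeds share identical populations.

**What the generator does not emulate:** motion artifacts, wavelength-
dependent optics, baseline wander correlated with force, arrhythmias,
inter-beat variability, nonlinear artery mechanics, and any dependence of
waveform shape on age or disease. Passing tests on this generator therefore
demonstrate that the pipeline recovers BP when the oscillometric bell is the
ground truth — not clinical accuracy.

## 3. Preprocessing (`ppgbp.preprocess`)

Filters are 4th-order Butterworth applied forward–backward (`sosfiltfilt`):
zero phase preserves beat timing, and the effective magnitude response is
|H|², which the tests verify against the analytic response within 1 dB.
Band-pass 0.8–8 Hz for PPG, low-pass 0.2 Hz for force.

Beat peaks: local maxima with a minimum spacing of fs·60/180 samples
(180 bpm ceiling); fewer than 4 peaks rejects the case. Envelope: cubic
spline through the (peak, value) knots, held constant beyond the outermost
peaks (polynomial extrapolation would swing wildly at the edges). On
Gaussian-modulated test tones the envelope recovers the modulator within 5 %
away from the edges.

Derivatives are unscaled forward differences with the last value repeated,
keeping stream lengths at 1720. The force segment is the 10-s window centred
on the envelope maximum of the channel with the globally largest envelope
value, linearly resampled to 215 samples (an effective 21.5 Hz); a centre
within 5 s of an edge shifts the window inside the recording and logs a
warning. Preprocessing is deterministic.

## 4. Network and training (`ppgbp.nn`, `ppgbp.model`)

The layer core is NumPy with hand-derived backward passes (verified against
numerical gradients). Convolutions use "same"-style padding with output
length ⌈L/stride⌉, which reproduces the published per-layer length chains
exactly: 1720→860→430→215→108 for the PPG streams and 215→108→54→27→14 for
the force stream. Residual blocks change both width and length, so skips are
1×1 convolutions with stride 2 plus batch norm — the standard down-sampling
projection. Batch norm uses batch statistics in training and running
statistics (momentum 0.1) at inference; dropout (rate 0.3) is inverted and
disabled at inference.

Optimization: Adam (β₁ 0.9, β₂ 0.999, lr 0.005), batch 64, coupled L2
penalty 5·10⁻³ on weights (not biases or BN parameters). Targets are
z-scored internally using the training-label mean/SD (stored in the
checkpoint; all reported estimates are in mmHg). With a bounded sigmoid
latent and a freshly initialized scalar head, raw-mmHg targets would spend
thousands of Adam steps just moving the output bias toward ~80 mmHg;
standardization keeps the published optimizer settings effective at desk
scale without changing the loss geometry.

Stage 1 trains one extractor per channel. Stage 2 freezes all nine
extractors (the staging is sequential by design; joint fine-tuning is out of
scope), caches their latents, and trains only the score perceptron (ω, b)
and a fresh 16→1 output layer. The stage-1 scalar heads are kept for
single-channel prediction and for ranking channels by validation MSE; that
ranking drives the hard top-k channel-selection variant, in which the k best
channels keep their softmax weights, renormalized to sum to one.

Epoch budgets are configurable; the desk-scale defaults are 20 epochs with
early stopping (patience 4) on a subject-disjoint validation split for
stage 1, and 150 epochs (patience 15) for the cheap stage 2. Determinism:
all initialization, shuffling and dropout derive from explicit seeds, so a
(data seed, training seed) pair reproduces results bit-for-bit.

Input-combination ablations (P+F, E+F, P+E+F) zero-mask the excluded stream
rather than re-architecting the extractor, so a single architecture serves
all modes.

## 5. Evaluation (`ppgbp.evaluate`)

Errors are estimate − reference; STD uses the N−1 denominator. Exact
equality of estimate and reference vectors short-circuits Pearson r to 1;
otherwise zero variance leaves r undefined (reported as missing). Bland–
Altman limits are mean difference ± 1.96 SD. The AAMI accuracy check is
|ME| ≤ 5 mmHg and STD ≤ 8 mmHg, boundaries inclusive. Cross-validation folds
partition *subjects*, never cases; pooled metrics are computed over the
concatenated held-out predictions (i.e. case-weighted — a fold-mean
definition would differ slightly for unequal folds). BP groups for the
attention-weight analysis use the standard clinical cut-offs: hypertensive
SBP ≥ 140 or DBP ≥ 90; hypotensive SBP ≤ 90 or DBP ≤ 60.

## 6. Benchmarks and problem sizes (`ppgbp.benchmark`)

The default benchmark generates 200 subjects × 5 cases (seed 7): fold 1 of a
subject-level 5-fold split (40 subjects) is held out for testing, and 20 %
of the remaining subjects form the early-stopping validation set. Two
non-learning baselines calibrate the result: the training-mean predictor,
and the envelope-peak oracle, which reads MAP as applied pressure at the
centre of the force segment and inverts the MAP formula with the training
population's mean PP. At these sizes the full DBP system reaches
ME ≈ −0.1 mmHg, STD ≈ 5.3 mmHg on held-out subjects versus ≈ 11.7 and
≈ 9.3 mmHg STD for the two baselines (one CPU core, ≈ 5 minutes).

The informative-channel benchmark pins the finger at the grid centre with a
tightly focused gain profile (spread 0.2), so only channel 5 carries the
oscillometric signal; note the shared force stream still lets every channel
regress MAP, so the margin that attention must detect is the envelope-borne
PP information. With converged extractors the centre channel's mean
attention weight exceeds twice uniform. The ablation benchmark trains one
single-channel extractor per input mode on the default dataset and compares
best validation MSE.

## 7. Known limitations

* The NumPy core is single-threaded and CPU-bound; it is adequate at desk
  scale but not a general training framework.
* The generator's bell-plus-gains world is far simpler than clinical data;
  absolute error numbers here say nothing about clinical accuracy.
* The attention analysis by BP group is only meaningful when the test set
  contains all three groups; small synthetic runs may leave a group empty
  (reported with count 0).
* SBP recovery is harder than DBP in this generator (SBP depends more
  strongly on the bell width, i.e. on envelope shape detail); the reference
  benchmark targets DBP, and SBP systems train with the same code path.
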