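# Methods

## Generative model of the synthetic sessions

Each recording channel is a sum of three parts, all in µV at 500 Hz:

1. **Broadband background.** Gaussian noise with power-law spectrum
   PSD ∝ f^−1 (spectrally shaped white noise, DC removed), in two parts: a
   component *shared by all channels* (default 12 µV RMS) standing in for
   volume-conducted distant activity and common-mode pickup, and an
   *independent per-channel* component (default 2 µV RMS).
2. **Narrowband rhythms.** For each band (mu 8–12 Hz, beta 18–26 Hz, alpha
   8–13 Hz) a unit-RMS carrier is built as 4th-order-Butterworth
   band-filtered white noise — band-filtered noise rather than sinusoids, so
   Welch peaks have realistic width. Channels are wired to *shared sources*:
   one sensorimotor source per hemisphere (C3/C5 and C4/C6), one midline
   source (Fz), and a posterior alpha source projecting to all channels.
   A channel's carrier is √c·(group carrier) + √(1−c)·(own carrier) with
   coherence c = 0.9, giving the cross-channel correlation structure that a
   spatial filter can exploit and a per-channel pipeline cannot.
3. **Class modulation.** Each task class multiplies selected
   (channel, band) amplitudes: ERD multiplier 0.6 (mu) and √0.6 (beta) on
   the contralateral central channels for hand imagery, on Fz (plus mild
   0.8 bilateral mu) for foot imagery, and ERS 2.5 on POz alpha for
   eyes-closed. Baseline amplitudes: mu 4.5, beta 2.25, alpha 3.0 µV RMS.
   Envelopes cross-fade over 0.5 s at segment boundaries (raised cosine), so
   there are no amplitude discontinuities; the 2 s post-transition discard
   makes the fade shape immaterial downstream.

Determinism: all randomness derives from `SimConfig.seed` through a
`SeedSequence` spawned per (subject, trial, stream), so a configuration
reproduces recordings byte-exactly.

**Calibration.** The background scale was set so that the classification
task is demanding but clearly learnable: with the full protocol (5 trials ×
4 × 60 s) a spatial CNN reaches ≈0.9 cross-validated accuracy on 4 s
windows (0.907 ± 0.042 SEM over folds in the README example), the PSDA+SVM route 0.6–0.77, and the channel-wise CNN in between —
the same ordering the spatial-first architecture shows on real
multichannel MI data. The common-mode-dominated regime (shared background ≫
per-channel signal) was chosen deliberately: it is the regime in which an
early spatial filter has a physical job to do (cancel the shared noise
before the nonlinearity), so the spatial-vs-standard contrast is a property
of the data rather than of optimizer luck.

**What the generator does not model:** eye-blink/EMG artifacts, electrode
impedance drift, nonstationary rhythm frequency, realistic forward-model
lead fields, inter-subject variability beyond the seed. Passing tests
therefore demonstrate that the *pipeline machinery* behaves as specified on
data with the assumed statistical structure — not that any accuracy figure
transfers to human recordings.

## Preprocessing

- Decimation 500→250 Hz: order-8 Butterworth low-pass at 0.34 × target rate
  applied forward–backward, then keep every 2nd sample. Only integer ratios
  are supported.
- Band-pass/high-pass: third-order Butterworth (4–33 Hz / 4 Hz). Filters run
  **causally by default** (forward only) so that offline cross-validation
  estimates what the streaming path can actually compute; zero-phase
  filtering is available behind `causal=False`.
- Rescaling: one affine map per continuous recording, all channels jointly,
  global min → −1 and max → +1, applied before windowing. Per-recording
  scope preserves inter-channel amplitude ratios (the spatial filter's
  input) and needs no fitted state offline; the streaming path instead
  freezes the extrema of the training recordings (no lookahead).
- Windowing: per class segment, drop the first 2 s, then windows of
  1/2/4 s advancing by length × (1 − overlap), quantized to whole samples,
  never crossing a segment boundary. The closed form
  floor((usable − length)/stride) + 1 gives 28 windows per 58 s usable
  segment at 4 s/50 %, hence 112 per trial and 2240 over 4 subjects ×
  5 trials.

## Classifiers

All three families consume identically preprocessed data.

**Spatial CNN.** Layer 1 is a spatial convolution whose kernel spans all six
channels (12 filters), i.e. learned virtual channels. Then two temporal
blocks: (i) band-forming temporal convolution (24 filters, 16 taps ≈ 64 ms),
batch-norm, **square**, average-pool (8), **log** — instantaneous log band
power, the quantity ERD/ERS modulates; (ii) temporal convolution (8 taps)
with batch-norm, ELU, average-pool (4); then dropout 0.25 throughout, a
flatten and a dense softmax. ≈50 k parameters at 4 s windows.

**Standard CNN.** Identical trunk structure, but every convolution has
spatial extent 1 (depthwise): channels are filtered, squared and pooled
independently and only the final dense layer mixes them. This is the
image-style "1×k kernel" CNN and isolates exactly one variable — whether a
cross-channel linear combination exists before the nonlinearity.

**PSDA + SVM.** Per window and channel, Welch PSD on the 512-point Hann
grid (shorter windows zero-padded so the feature grid is identical across
window lengths), bins restricted to 4–33 Hz and concatenated; features are
standardized (fit on training folds only) and classified by an SVM with an
inhomogeneous cubic kernel (γ⟨x,x′⟩+1)³, C = 1, one-vs-one. The
inhomogeneous form matters: the homogeneous cubic (coef0 = 0) discards all
lower-order terms and performs near chance on these features.

**Training protocol (CNNs).** Adam (10⁻³ default), batch 64, at most 200
epochs, early stopping when validation accuracy has not improved for 20
epochs, best-epoch weights restored. Networks are float32 internally;
gradients of every layer are verified against finite differences in the
test suite. Desk-scale tests shorten the schedule (learning rate 3×10⁻³,
40–60 epoch cap) and the sessions (12 s segments); these are problem-size
choices for the scaled-down test configurations, stated in each test.

## Evaluation

- **Cross-validation:** fivefold leave-one-recording-out per subject;
  recording i is the validation fold, the others train. For the CNNs the
  held-out recording also drives early stopping, mirroring the training
  protocol's validation-based stopping. Fold confusion matrices pool by
  summation; accuracies are reported per fold, pooled, and mean ± SEM
  (SD/√n).
- **ITR:** the Wolpaw form
  [log₂N + A log₂A + (1−A) log₂((1−A)/(N−1))]·60/w, with the 0·log 0 = 0
  limits at A ∈ {0, 1}; the raw value is returned (no clipping at zero).
- **Alpha SNR:** on 4 Hz-high-passed 500 Hz data, per 5 s window: Welch PSD
  with a full-window Hann taper zero-padded to 4096 points; the signal
  amplitude is √PSD at the largest spectral *peak* (local maximum, matching
  a peak-finding readout) in 8–13 Hz, the noise amplitude the largest √PSD
  in 4–40 Hz outside ±2 Hz of that peak; SNR = 10·log₁₀((A_s/A_n)²).
  The ±2 Hz exclusion half-width and the 4–40 Hz noise range are
  configurable; windows with no in-band peak are skipped with a warning.

## Online control scheme

The stream classifies the trailing 4 s window every 0.16 s (window start
quantized to whole samples), preprocessing causally with training-frozen
rescale extrema. Two consecutive agreeing classifications confirm a
command; pairs do not overlap, so sustained intent re-confirms every
0.32 s. The game spawns a cue at t = 1 s and every 4 s thereafter for 240 s
(60 cues; Blue→feet, Green→left hand, Red→right hand, Yellow→eyes closed).
A cue's response window runs to the next spawn. By default a wrong confirmed
command yields feedback but leaves the cue active until a matching command
or the window end — the behaviour implied by a rhythm game in which a wrong
action shows "Wrong" and the cube stays; the stricter first-command-decides
rule is available as `resolve="first"`. Note the physics of the trailing
window: just after a spawn the window still contains mostly the previous
task, so the first confirmations in a cue window are systematically stale;
under the first-command rule a compliant player would score near zero, which
is why it is not the default.

## Design choices made where the protocol leaves room

- Within-trial class order (eyes-closed first, then left hand, right hand,
  feet) is a convention, configurable in `make_protocol`.
- Welch overlap for the 512-point classification PSD: 50 %.
- ERD/ERS map reference: pooled mean of the other classes (no rest
  condition exists in the protocol); configurable.
- "4096 Hann window" for the SNR estimate is read as FFT length with a
  full-window taper; a shorter taper can be passed explicitly.
- SVM regularization C = 1 and feature standardization are defaults exposed
  in `train_svm_psda`.
- EDF files are written by a small built-in EDF+ writer (16-bit, 1 s
  records, annotations as TALs) and read back through `mne`, which doubles
  as an independent check of the writer.

## Known limitations

- The CNNs run on a single CPU in plain numpy; they are sized for
  hundreds-of-windows training sets, not GPU-scale search.
- Accuracy figures on synthetic data depend on the calibrated noise regime
  and should be read as *relative* statements (family orderings, window-
  length trends), not predictions for human subjects.
- The streaming simulator models the signal path only — no transport
  latency, no human reaction-time variability beyond the 2 s discard
  convention, no artifact rejection.
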