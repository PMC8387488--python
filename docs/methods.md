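# Methods

## The classification problem

Adventitious lung sounds — crackles, wheezes, rhonchi — superimposed on the
normal breath sound are diagnostic for parenchymal and airway disease, but
their interpretation by ear requires expertise. The pipeline here treats the
problem as image classification: short audio windows become three-channel
time–frequency images, a frozen convolutional network maps them to feature
tensors, and a shallow trainable head assigns class probabilities. Decisions
can be made in one flat 4-class pass or in two stages (normal vs abnormal,
then crackle/wheeze/rhonchus), the two-stage route mirroring clinical triage:
the binary gate is the screening decision, the subtype the differential.

## The synthetic corpus

Clinical auscultation databases are generally not shareable, so the
`sound_synth` module generates a corpus with the documented acoustics of each
sound class rather than the idiosyncrasies of any particular hospital's
recordings.

**Breath base.** Normal (vesicular) breath sound is modelled as band-limited
noise, 100–1800 Hz with 1/f power weighting, amplitude-modulated by a
repeating respiratory-cycle envelope. The respiratory rate is drawn per
recording from 15–20 breaths/min (3–4 s per cycle, the normal adult range);
inspiration occupies the first 40% of each cycle as a full-height half-sine
bump, expiration a 0.7-height bump, with a 5% floor. The 100–1800 Hz
pink-weighted band is this package's own choice — normal-breath-sound
spectra are broadband and low-frequency-dominant, but no canonical spectrum
exists to copy.

**Events.** Each class has an acoustic profile:

| class          | waveform                        | center freq       | duration | phase                  |
|----------------|---------------------------------|-------------------|----------|------------------------|
| fine crackle   | exponentially damped sinusoid   | 650 Hz            | 5 ms     | inspiratory            |
| coarse crackle | exponentially damped sinusoid   | 350 Hz            | 15 ms    | inspiratory            |
| wheeze         | quasi-sinusoid                  | 100–5000 Hz range | > 80 ms  | expiratory-dominant    |
| rhonchus       | quasi-sinusoid                  | 150 Hz            | > 80 ms  | expiratory-dominant    |
| stridor        | quasi-sinusoid                  | 500 Hz            | > 80 ms  | inspiratory            |
| pleural rub    | rhythmic short low-freq. sounds | 250 Hz            | ~300 ms  | both                   |

Damped signals have no hard endpoint, so an event's *duration* is
operationalized as the span from onset to the 99%-cumulative-energy point;
the crackle damping constant is set so this span equals the nominal duration
(energy envelope e^(−2t/τ), 99% at t = τ·ln(100)/2). Continuous sounds are a
fundamental plus weak harmonics (amplitudes 1 / 0.15 / 0.05), slow 2–6 Hz
amplitude modulation (depth 0.3) and tapered edges, giving low spectral
flatness relative to noise. Wheeze fundamentals are drawn log-uniformly from
200–1600 Hz: the admissible band extends to 5 kHz, but clinical wheeze
energy concentrates well below it and the upper part of the band is covered
by harmonics; durations ≤ 80 ms are flagged with a warning but still
generated. Small per-event jitter (±3% frequency, amplitude, modulator
phase) keeps events from being identical.

**Composition.** Events are placed inside phase-consistent windows of the
known envelope: crackles and stridor strictly inspiratory, wheeze/rhonchus
expiratory with probability 0.8 (the conventional "expiratory >
inspiratory"). SNR is defined on the event's active span, not the whole
recording — otherwise a 5-ms crackle's contribution to a 15-s recording's
power would be negligible at any audible level. The composite is renormalized
into [−1, 1] only if it clips, and the scale is recorded. Default event SNR
is 10 dB; "easy" test corpora use 20 dB.

**Default corpus.** 1222 normal, 297 crackle, 298 wheeze, 101 rhonchus
(1918 recordings, 63.7% normal) — the composition of the clinical corpus the
simulator stands in for. Recordings are 10–20 s at 8 kHz, 3–8 events each,
PCM-16 on disk. 8 kHz is chosen because every default class frequency sits
below 2 kHz (Nyquist margin > 2×); profile frequencies are validated against
Nyquist. Stridor and pleural rub are implemented but excluded from the
4-class label set; they can only be emitted as unlabeled distractors.

**What the simulator does not capture.** Body-surface transfer functions,
airflow physiology, mixed-class recordings, inter-patient variability, real
ward noise statistics. Passing tests on this corpus demonstrates that the
pipeline recovers class structure that is genuinely present in the signal;
it does not certify clinical-grade accuracy on real recordings.

## Preprocessing

Recordings are segmented into 6-s windows with 50% overlap (hop 3 s); 6 s
covers two to three respiratory cycles, the minimum context for judging a
lung sound. Only fully contained windows are emitted
(count = ⌊(T−6)/3⌋ + 1, so a 14.5-s recording yields exactly 3), recordings
of 3–6 s are reflection-padded to one window (rejecting them would discard
plausible clinical clips), and anything under 3 s is rejected.

Each window becomes three 256×256 channels, in fixed order:

1. **log-Mel** — 128 HTK-scale triangular Mel bands over a centered,
   reflection-padded Hann STFT (n_fft 1024, hop 256 at 8 kHz), log with a
   1e−10 power floor. These sizes put the native image within 2× of 256 on
   both axes before the bilinear resize.
2. **HPSS average** — median-filter harmonic/percussive separation (kernel
   31) with soft masks (p = 2) that sum to one per bin, then the mean of the
   harmonic and percussive Mel power, log-scaled. This channel emphasizes
   the sustained/transient split that distinguishes wheezes from crackles.
3. **delta** — Savitzky–Golay time derivative (window 9, order 1) of the
   log-Mel channel. The derivative is taken on the log matrix so it measures
   relative spectral change.

Each channel is min–max normalized to [0, 1] per segment (the raw range is
recorded); a uniform channel maps to zeros. The extractor then applies its
own input convention (ImageNet mean/std for the named architectures,
identity for the fallback).

## Feature extraction

Extractors are frozen convolutional networks with seeded random (He-scaled
Gaussian) weights. The registry reproduces the output signature of each
benchmark architecture exactly — VGG16/19 → 8×8×512, ResNet50/101 → 8×8×2048,
DenseNet201 → 8×8×1920, InceptionV3 (valid-padded stem) → 6×6×2048 on a
256×256 input — using thin (32-channel) intermediate layers so the forward
pass stays cheap on one CPU; `random_fallback` (8×8×64) is the default for
fast experiments. Random convolutional projections are untrained but
information-preserving, which is sufficient for the shallow heads to learn
on and keeps every run deterministic and offline. Pretrained ImageNet
weights are deliberately unsupported (`pretrained=True` raises): they would
require a deep-learning runtime and a network download, and nothing in the
package depends on them.

Frozen-ness is a contract: extractor parameters are hashed, and the hash is
unchanged by feature extraction or downstream head training.

## Classifier heads

**One-layer CNN** (primary): one 3×3 convolution (64 filters, ReLU) over the
feature map, global average pooling, linear softmax layer; cross-entropy
with inverse-frequency class weights, Adam (lr 1e−3), 30 epochs, batch 32.
Class weighting matters because of the 12:1 normal:rhonchus imbalance —
without it the smallest class collapses. When a validation set is supplied,
the epoch with the best validation accuracy is kept. Implemented in numpy;
patch matrices are built per minibatch so wide (2048-channel) feature maps
never materialize a multi-gigabyte array.

**Linear SVM** (comparison): standardized flattened features into a
linear-kernel SVM (balanced class weights); pseudo-probabilities from a
softmax over decision scores, which suffices for ranking (ROC) and argmax
labels.

Argmax ties break to the lowest class index. Two-stage composite
probabilities follow the product rule and sum to one by construction.
Recording-level labels, when wanted, are the argmax of the mean segment
probability vector.

## Evaluation protocol

A recording-level, label-stratified 80/20 train/test split, then a
stratified 5-fold partition of the 80%: each training recording serves once
for validation and four times for training. Splitting by recording is
essential — adjacent windows overlap by half, so segment-level splits would
leak test audio into training. The held-out test set is scored by the
ensemble mean of the five fold models' probabilities.

Metrics: accuracy, per-class precision/recall/F1 (zero denominators return
0 with a flag), macro averages, confusion matrix; one-vs-rest ROC per class
with trapezoidal AUC, Hanley–McNeil 95% CI, and the unweighted class mean as
"mean AUC". The benchmark harness runs every (extractor, head) pair under
the identical fold plan.

## Numerical and testing choices

* Every operation is a pure function of (arguments, seed); corpora draw
  per-recording generators from a seed sequence, so datasets are reproducible
  recording-by-recording and two identical runs produce byte-identical
  evaluation reports.
* Test corpora are sized for a single CPU: 60 recordings (15/class, 8–12 s,
  20 dB SNR) for the parameter-recovery check, 46 majority-normal recordings
  for the imbalance/permutation checks, the full 1918-recording default
  corpus only where its composition itself is under test.
* The permutation null (shuffled labels → accuracy ≈ majority-class rate)
  is checked with the unweighted CNN head: an unweighted fit on
  label-shuffled imbalanced data collapses to the majority class, which is
  exactly the null the check encodes. The class-weighted heads used for real
  training instead converge to the uniform prior under shuffling.
* AUC is validated against brute-force Mann–Whitney pair counting; the
  segment-count formula against a brute-force window enumerator; crackle
  spectra/durations against their closed-form profiles.

## Known limitations

* Random-weight extractors are weaker than pretrained ones; reported
  accuracies on the synthetic corpus are a floor, not an estimate of what
  pretrained features would achieve.
* The simulator's normal class is a single noise model; real normal
  recordings vary by site, device, and patient.
* Wheeze fundamentals above 1.6 kHz and mixed-class recordings are not
  generated by default.
* SVM probabilities are monotone transforms of margins, not calibrated
  posteriors; use the CNN head where probability magnitudes matter.
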