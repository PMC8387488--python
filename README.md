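# lungsound

Automated classification of chest-auscultation recordings into **normal**,
**crackle**, **wheeze**, and **rhonchus**, for researchers working on
adventitious lung-sound detection who need a complete, trainable pipeline
without access to a clinical recording database.

The package has two halves:

1. **A synthetic auscultation simulator.** Clinical respiratory-sound corpora
   are rarely shareable, so the simulator generates labeled recordings with
   the acoustic structure described in the pulmonology literature: a normal
   breath-sound base (band-limited pink-weighted noise modulated by an
   inspiration/expiration envelope at 15–20 breaths/min), with superimposed
   events — crackles as exponentially damped sinusoids
   (fine ≈ 650 Hz / ≈ 5 ms, coarse ≈ 350 Hz / ≈ 15 ms, inspiratory), wheezes
   and rhonchi as continuous quasi-sinusoids (> 80 ms; rhonchus ≈ 150 Hz;
   predominantly expiratory). The default corpus composition is
   1222 / 297 / 298 / 101 recordings (normal / crackle / wheeze / rhonchus),
   the class balance of the clinical setting the simulator emulates. Ward
   contaminants (cough, voice, heart sounds, monitor alarms) can be mixed in.
2. **The classification pipeline.** Recordings are cut into 6-s windows with
   50% overlap; each window becomes a 3×256×256 image: the log-Mel
   spectrogram, the log of the harmonic/percussive-average Mel spectrogram
   (median-filter HPSS), and the log-Mel time derivative. A frozen
   convolutional feature extractor maps each stack to a feature tensor
   (a registry mirrors the output signatures of InceptionV3, DenseNet201,
   ResNet50/101, VGG16/19, with seeded random weights — deterministic and
   download-free), and a shallow head classifies: a one-layer CNN
   (3×3 conv → global average pooling → softmax) or a linear SVM. A
   two-stage scheme first separates normal from abnormal
   (P(normal) vs P(abnormal)), then assigns abnormal segments to
   crackle/wheeze/rhonchus with composite probabilities
   P(c) = P(abnormal)·P(c | abnormal). Evaluation uses a recording-level
   stratified 80/20 split with 5-fold cross-validation, per-class
   precision/recall/F1, and one-vs-rest ROC with trapezoidal AUC and
   Hanley–McNeil 95% confidence intervals.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import lungsound as ls

# 1. a synthetic corpus: 10 recordings per class at a benign 20 dB SNR
cfg = ls.SynthDatasetConfig(
    counts={"normal": 10, "crackle": 10, "wheeze": 10, "rhonchus": 10},
    recording_duration_s=(8.0, 12.0), snr_db=20.0, seed=7,
)
recordings, manifest = ls.generate_dataset(cfg)

# 2. segment and build 3x256x256 spectrogram stacks
stacks, labels, rec_ids = [], [], []
for rec in recordings:
    for seg in ls.segment(rec.as_waveform(), parent_id=rec.meta["id"]):
        stacks.append(ls.build_stack(seg))
        labels.append(rec.label)
        rec_ids.append(rec.meta["id"])

# 3. frozen feature extractor (seeded random weights; no download)
extractor = ls.get_extractor("random_fallback", seed=0)
features = ls.extract_features(extractor, stacks)

# 4. recording-level 80/20 split + 5-fold CV with the one-layer CNN head
plan = ls.make_fold_plan(manifest["id"], manifest["label"], seed=0)
report = ls.run_cv(features, labels, rec_ids, plan,
                   "cnn_one_layer", "four_class_flat", ls.TrainConfig(seed=0))
print(f"fold-mean accuracy: {report.fold_mean['accuracy']:.3f}")
print(f"held-out test accuracy: {report.test['accuracy']:.3f}")
print(f"held-out mean one-vs-rest AUC: {report.test['mean_auc']:.3f}")
```

Output:

```
fold-mean accuracy: 0.618
held-out test accuracy: 0.500
held-out mean one-vs-rest AUC: 0.885
```

70 six-second segments come out of the 40 recordings; the fold-mean accuracy
(0.618) is the average validation accuracy over the five folds, far above the
0.25 chance rate for four balanced classes, and the held-out AUC (0.885) is
the unweighted mean of the four one-vs-rest AUCs on the 20% of recordings
never seen in training. Larger corpora and the wider extractors push both up;
this miniature run is sized to finish in well under a minute.

A `lungsound` console script exposes the same stages
(`synth`, `preprocess`, `extract`, `train`, `predict`, `evaluate`,
`benchmark`); run `lungsound --help` for options.

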