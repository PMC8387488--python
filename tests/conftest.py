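"""Shared fixtures: small synthetic corpora reused across the suite.

Session scope keeps the expensive pieces (waveform synthesis, spectrogram
stacks, feature extraction) computed once.
"""

import numpy as np
import pytest

import lungsound as ls


def _stacks_for(recordings):
    stacks, labels, rec_ids = [], [], []
    for r in recordings:
        for s in ls.segment(r.as_waveform(), parent_id=r.meta["id"]):
            stacks.append(ls.build_stack(s))
            labels.append(r.label)
            rec_ids.append(r.meta["id"])
    return stacks, labels, rec_ids


@pytest.fixture(scope="session")
def easy_corpus():
    """60 recordings, 15 per class, benign 20 dB SNR: separable by design."""
    cfg = ls.SynthDatasetConfig(
        counts={"normal": 15, "crackle": 15, "wheeze": 15, "rhonchus": 15},
        recording_duration_s=(8.0, 12.0),
        snr_db=20.0,
        seed=11,
    )
    return ls.generate_dataset(cfg)


@pytest.fixture(scope="session")
def easy_stacks(easy_corpus):
    recs, _ = easy_corpus
    return _stacks_for(recs)


@pytest.fixture(scope="session")
def fallback_features(easy_stacks):
    stacks, labels, rec_ids = easy_stacks
    ext = ls.get_extractor("random_fallback", seed=0)
    return ls.extract_features(ext, stacks), labels, rec_ids


@pytest.fixture(scope="session")
def easy_plan(easy_corpus):
    _, man = easy_corpus
    return ls.make_fold_plan(man["id"], man["label"], seed=0)


@pytest.fixture(scope="session")
def skewed_corpus():
    """Majority-normal mix echoing the clinical class imbalance."""
    cfg = ls.SynthDatasetConfig(
        counts={"normal": 25, "crackle": 7, "wheeze": 7, "rhonchus": 7},
        recording_duration_s=(6.0, 8.0),
        snr_db=20.0,
        seed=13,
    )
    return ls.generate_dataset(cfg)


@pytest.fixture(scope="session")
def skewed_features(skewed_corpus):
    recs, _ = skewed_corpus
    stacks, labels, rec_ids = _stacks_for(recs)
    ext = ls.get_extractor("random_fallback", seed=0)
    feats = ls.extract_features(ext, stacks)
    return np.stack([f.tensor for f in feats]), labels, rec_ids
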