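"""Acoustic fidelity of the simulator: event spectra and durations, breath
envelope timing, phase-aware composition, dataset determinism, contaminants."""

import hashlib

import numpy as np
import pytest

import lungsound as ls
from lungsound.sound_synth import breath_envelope

SR = 8000


# --- breath base ------------------------------------------------------------

def test_cycle_duration_in_normal_range():
    """15-20 breaths/min corresponds to 3-4 s per respiratory cycle."""
    for bpm in (15.0, 17.0, 20.0):
        cyc = ls.BreathCycleParams(breaths_per_min=bpm).cycle_s
        assert 3.0 <= cyc <= 4.0
    assert ls.BreathCycleParams(breaths_per_min=17.0).cycle_s == pytest.approx(
        60 / 17
    )


def test_envelope_is_periodic_with_cycle():
    p = ls.BreathCycleParams(breaths_per_min=17.0)
    t = np.linspace(0, p.cycle_s, 500, endpoint=False)
    assert np.allclose(
        breath_envelope(t, p), breath_envelope(t + p.cycle_s, p), atol=1e-12
    )


def test_breath_base_zero_amplitude_is_silent():
    p = ls.BreathCycleParams(amplitude=0.0)
    rec = ls.synthesize_breath_base(p, 10.0, SR, seed=0)
    assert np.array_equal(rec.samples, np.zeros(10 * SR))


def test_breath_base_deterministic_and_validated():
    p = ls.BreathCycleParams()
    a = ls.synthesize_breath_base(p, 8.0, SR, seed=5)
    b = ls.synthesize_breath_base(p, 8.0, SR, seed=5)
    assert np.array_equal(a.samples, b.samples)
    assert a.label == "normal"
    assert a.samples.size == 8 * SR
    with pytest.raises(ValueError):  # shorter than one cycle
        ls.synthesize_breath_base(p, 2.0, SR, seed=0)
    with pytest.raises(ValueError):  # band above Nyquist
        bad = ls.BreathCycleParams(base_noise_band_hz=(100.0, 5000.0))
        ls.synthesize_breath_base(bad, 10.0, SR, seed=0)


# --- transients -------------------------------------------------------------

@pytest.mark.parametrize(
    "name, freq, dur_ms",
    [("fine_crackle", 650.0, 5.0), ("coarse_crackle", 350.0, 15.0)],
)
def test_crackle_spectral_and_duration_recovery(name, freq, dur_ms):
    x = ls.synthesize_transient(ls.PROFILES[name], SR, seed=0)
    assert abs(ls.dominant_frequency(x, SR) - freq) <= 0.10 * freq
    meas = ls.effective_duration(x, SR) * 1000.0
    assert abs(meas - dur_ms) <= 0.20 * dur_ms


def test_crackle_envelope_decays_below_one_percent():
    x = ls.synthesize_transient(ls.PROFILES["fine_crackle"], SR, seed=0)
    tail = np.max(np.abs(x[-8:]))
    assert tail < 0.01 * np.max(np.abs(x))


def test_transient_rejects_super_nyquist_frequency():
    import dataclasses

    hot = dataclasses.replace(ls.PROFILES["fine_crackle"], center_freq_hz=4500.0)
    with pytest.raises(ValueError):
        ls.synthesize_transient(hot, SR, seed=0)


def test_transient_deterministic_given_seed():
    a = ls.synthesize_transient(ls.PROFILES["coarse_crackle"], SR, seed=3)
    b = ls.synthesize_transient(ls.PROFILES["coarse_crackle"], SR, seed=3)
    assert np.array_equal(a, b)


# --- continuous sounds ------------------------------------------------------

def test_rhonchus_dominant_frequency_near_150():
    x = ls.synthesize_continuous(ls.PROFILES["rhonchus"], 300.0, SR, seed=0)
    f = ls.dominant_frequency(x, SR)
    assert abs(f - 150.0) <= 15.0


def test_wheeze_tone_peaks_at_requested_frequency():
    """FFT argmax of a 400 Hz, 250 ms wheeze lands on the 400 Hz bin."""
    x = ls.synthesize_continuous(
        ls.PROFILES["wheeze"], 250.0, SR, seed=0, freq_hz=400.0
    )
    n = 1 << 16
    mag = np.abs(np.fft.rfft(x, n=n))
    mag[0] = 0
    peak = np.fft.rfftfreq(n, 1 / SR)[np.argmax(mag)]
    assert abs(peak - 400.0) < 10.0


def test_pure_tone_limit_has_near_zero_flatness():
    x = ls.synthesize_continuous(
        ls.PROFILES["rhonchus"], 300.0, SR, seed=0,
        harmonics=(1.0,), mod_depth=0.0,
    )
    noise = np.random.default_rng(0).standard_normal(x.size)
    assert ls.spectral_flatness(x) < 0.01
    assert ls.spectral_flatness(x) < 0.05 * ls.spectral_flatness(noise)


def test_short_continuous_duration_flags_warning_but_generates():
    with pytest.warns(UserWarning):
        x = ls.synthesize_continuous(ls.PROFILES["rhonchus"], 50.0, SR, seed=0)
    assert x.size == int(0.05 * SR)


# --- composition ------------------------------------------------------------

def _base(seed=1, bpm=17.0, dur=10.0):
    return ls.synthesize_breath_base(
        ls.BreathCycleParams(breaths_per_min=bpm), dur, SR, seed=seed
    )


def test_crackles_placed_in_inspiratory_windows():
    base = _base()
    params = ls.BreathCycleParams(breaths_per_min=17.0)
    evs = [
        (ls.synthesize_transient(ls.PROFILES["fine_crackle"], SR, seed=i),
         "fine_crackle")
        for i in range(5)
    ]
    rec = ls.compose_recording(base, evs, 10.0, seed=2)
    assert rec.label == "crackle"
    assert len(rec.meta["events"]) == 5
    for ev in rec.meta["events"]:
        phase = (ev["onset_s"] % params.cycle_s) / params.cycle_s
        assert phase < params.insp_frac


def test_expiratory_dominant_placement_for_continuous_sounds():
    base = _base(dur=20.0)
    params = ls.BreathCycleParams(breaths_per_min=17.0)
    evs = [
        (ls.synthesize_continuous(ls.PROFILES["rhonchus"], 250.0, SR, seed=i),
         "rhonchus")
        for i in range(30)
    ]
    rec = ls.compose_recording(base, evs, 10.0, seed=4)
    phases = [
        (ev["onset_s"] % params.cycle_s) / params.cycle_s
        for ev in rec.meta["events"]
    ]
    exp_frac = np.mean([p >= params.insp_frac for p in phases])
    assert exp_frac > 0.5  # expiratory majority (expected 80%)


def test_no_events_yields_normal_identity():
    base = _base()
    rec = ls.compose_recording(base, [], 10.0, seed=0)
    assert rec.label == "normal"
    assert np.array_equal(rec.samples, base.samples)


def test_minus_infinity_snr_leaves_base_unchanged():
    base = _base()
    evs = [(ls.synthesize_transient(ls.PROFILES["fine_crackle"], SR, 0),
            "fine_crackle")]
    rec = ls.compose_recording(base, evs, -np.inf, seed=0)
    assert np.allclose(rec.samples, base.samples, atol=1e-12)
    assert rec.label == "crackle"  # labels reflect intent, not energy


def test_abnormal_label_requires_events():
    with pytest.raises(ValueError):
        ls.compose_recording(_base(), [], 10.0, seed=0, label="wheeze")


def test_composition_energy_bound_and_onset_count():
    """E(composite) <= (sqrt(E_base) + sum sqrt(E_event))^2 before renorm."""
    base = _base()
    evs = [
        (ls.synthesize_transient(ls.PROFILES["coarse_crackle"], SR, seed=i),
         "coarse_crackle")
        for i in range(4)
    ]
    snr = 12.0
    rec = ls.compose_recording(base, evs, snr, seed=9)
    assert len(rec.meta["events"]) == len(evs)
    comp = rec.samples / rec.meta["renorm"]
    e_base = np.sum(base.samples**2)
    e_events = 0.0
    for ev in rec.meta["events"]:
        i0 = int(round(ev["onset_s"] * SR))
        i1 = min(i0 + int(round(ev["duration_s"] * SR)), base.samples.size)
        p_slice = np.mean(base.samples[i0:i1] ** 2)
        e_events += 10 ** (snr / 10) * p_slice * (i1 - i0)
    bound = (np.sqrt(e_base) + len(evs) * np.sqrt(e_events)) ** 2
    assert np.sum(comp**2) <= bound * 1.01


# --- dataset ----------------------------------------------------------------

def test_tiny_dataset_counts_and_invariants():
    cfg = ls.SynthDatasetConfig(
        counts={"normal": 3, "crackle": 2, "wheeze": 2, "rhonchus": 2},
        recording_duration_s=(5.0, 7.0),
        seed=21,
    )
    recs, man = ls.generate_dataset(cfg)
    assert len(recs) == 9
    assert man["label"].value_counts().to_dict() == {
        "normal": 3, "crackle": 2, "wheeze": 2, "rhonchus": 2
    }
    for rec in recs:
        assert np.max(np.abs(rec.samples)) <= 1.0
        assert rec.samples.size == int(round(rec.duration_s * SR))
    abn = man[man["label"] != "normal"]
    assert (abn["n_events"] >= cfg.events_per_recording[0]).all()


def test_dataset_checksums_reproducible_across_runs():
    cfg = ls.SynthDatasetConfig(
        counts={"crackle": 10}, recording_duration_s=(5.0, 6.0), seed=42
    )
    sums = []
    for _ in range(2):
        recs, man = ls.generate_dataset(cfg)
        assert len(recs) == 10
        sums.append(
            [hashlib.sha256(r.samples.tobytes()).hexdigest() for r in recs]
        )
    assert sums[0] == sums[1]


def test_empty_counts_give_empty_dataset():
    cfg = ls.SynthDatasetConfig(counts={}, seed=0)
    cfg = ls.SynthDatasetConfig(
        counts={"normal": 0, "crackle": 0, "wheeze": 0, "rhonchus": 0}, seed=0
    )
    recs, man = ls.generate_dataset(cfg)
    assert recs == [] and len(man) == 0


def test_config_validation():
    with pytest.raises(ValueError):
        ls.SynthDatasetConfig(counts={"sigh": 3})
    with pytest.raises(ValueError):
        ls.SynthDatasetConfig(counts={"normal": -1})
    with pytest.raises(ValueError):
        ls.SynthDatasetConfig(recording_duration_s=(2.0, 3.0))


def test_save_dataset_writes_wavs_and_manifest(tmp_path):
    cfg = ls.SynthDatasetConfig(
        counts={"normal": 2, "wheeze": 1}, recording_duration_s=(5.0, 6.0), seed=3
    )
    recs, man = ls.generate_dataset(cfg)
    ls.save_dataset(recs, man, tmp_path)
    assert (tmp_path / "manifest.csv").exists()
    for rec_id in man["id"]:
        w = ls.read_wav(tmp_path / f"{rec_id}.wav")
        assert w.sample_rate_hz == SR


# --- contaminants -----------------------------------------------------------

def _band_power(x, rate, lo, hi):
    f = np.fft.rfftfreq(x.size, 1 / rate)
    p = np.abs(np.fft.rfft(x)) ** 2
    return p[(f >= lo) & (f < hi)].sum()


def test_heart_sound_adds_low_frequency_energy():
    rec = _base(seed=8)
    out = ls.add_contaminants(rec, ["heart_sound"], level_db=0.0, seed=0)
    before = _band_power(rec.samples, SR, 20, 200)
    after = _band_power(out.samples, SR, 20, 200)
    assert after > 2.0 * before
    assert out.label == rec.label
    assert out.meta["contaminants"][0]["kind"] == "heart_sound"


def test_empty_contaminant_set_is_identity():
    rec = _base(seed=8)
    out = ls.add_contaminants(rec, [], level_db=0.0, seed=0)
    assert np.array_equal(out.samples, rec.samples)


def test_very_low_level_contaminant_is_below_minus50db():
    rec = _base(seed=8)
    out = ls.add_contaminants(rec, ["cough"], level_db=-60.0, seed=0)
    residual = np.mean((out.samples - rec.samples) ** 2)
    assert residual < 10 ** (-50 / 10) * np.mean(rec.samples**2)


def test_unknown_contaminant_kind_rejected():
    with pytest.raises(ValueError):
        ls.add_contaminants(_base(), ["thunder"], level_db=0.0, seed=0)
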