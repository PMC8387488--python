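"""Synthetic respiratory-sound generator.

Emulates a chest-auscultation corpus: a normal breath-sound base (band-limited
pink-weighted noise, amplitude-modulated by a repeating inspiration/expiration
envelope at 15-20 breaths/min) with adventitious events superimposed at
phase-appropriate times:

* **crackles** — short explosive transients modelled as exponentially damped
  sinusoids (fine: ~650 Hz / ~5 ms; coarse: ~350 Hz / ~15 ms), inspiratory;
* **wheezes** — continuous quasi-sinusoids (>80 ms), predominantly expiratory;
* **rhonchi** — continuous low-pitched quasi-sinusoids (~150 Hz, >80 ms),
  predominantly expiratory;
* **stridor / pleural rub** — extra profiles available as unlabeled
  distractors only, never part of the 4-class label set.

"Duration" of an event is operationalized as the span from onset to the
99%-cumulative-energy point: damped signals have no hard endpoint, and the
damping constant of a crackle is chosen so that this span equals the nominal
duration. SNR is defined on the event's active span, not the whole recording,
so short crackles do not vanish at realistic levels.

All operations are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import Waveform, write_wav

__all__ = [
    "AcousticProfile",
    "BreathCycleParams",
    "SynthDatasetConfig",
    "LabeledRecording",
    "PROFILES",
    "LABELS",
    "breath_envelope",
    "synthesize_breath_base",
    "synthesize_transient",
    "synthesize_continuous",
    "compose_recording",
    "generate_dataset",
    "save_dataset",
    "add_contaminants",
    "effective_duration",
    "dominant_frequency",
    "spectral_flatness",
]

LABELS = ("normal", "crackle", "wheeze", "rhonchus")

# map of event profile -> 4-class recording label
_EVENT_LABEL = {
    "fine_crackle": "crackle",
    "coarse_crackle": "crackle",
    "wheeze": "wheeze",
    "rhonchus": "rhonchus",
}

_CONTAMINANT_KINDS = ("cough", "voice_like", "heart_sound", "alarm")

# ln(100)/2: a damped sinusoid with energy envelope exp(-2t/tau) accumulates
# 99% of its energy by t = tau * ln(100)/2
_E99 = float(np.log(100.0) / 2.0)


@dataclass(frozen=True)
class AcousticProfile:
    """Acoustic fingerprint of one adventitious-sound class.

    ``center_freq_hz`` is a scalar for classes with a characteristic
    frequency, or a (low, high) admissible range for wheeze.
    """

    class_name: str
    waveform_family: str  # damped_deflection | sinusoid | rhythmic_short_sounds
    center_freq_hz: float | tuple[float, float]
    duration_ms: float
    phase_bias: str  # inspiratory | expiratory_dominant | both
    pitch_class: str  # high | low


PROFILES: dict[str, AcousticProfile] = {
    "fine_crackle": AcousticProfile(
        "fine_crackle", "damped_deflection", 650.0, 5.0, "inspiratory", "high"
    ),
    "coarse_crackle": AcousticProfile(
        "coarse_crackle", "damped_deflection", 350.0, 15.0, "inspiratory", "low"
    ),
    "wheeze": AcousticProfile(
        "wheeze", "sinusoid", (100.0, 5000.0), 250.0, "expiratory_dominant", "high"
    ),
    "rhonchus": AcousticProfile(
        "rhonchus", "sinusoid", 150.0, 250.0, "expiratory_dominant", "low"
    ),
    "stridor": AcousticProfile(
        "stridor", "sinusoid", 500.0, 250.0, "inspiratory", "high"
    ),
    "pleural_rub": AcousticProfile(
        "pleural_rub", "rhythmic_short_sounds", 250.0, 300.0, "both", "low"
    ),
}

# wheeze fundamentals are drawn from this sub-range of the admissible band;
# clinical wheeze energy concentrates well below the band's upper edge, and
# harmonics fill in the rest
WHEEZE_SAMPLING_RANGE_HZ = (200.0, 1600.0)


@dataclass(frozen=True)
class BreathCycleParams:
    """Respiratory-cycle model for the normal breath-sound base.

    Defaults give a 3-4 s cycle (15-20 breaths/min, the normal adult range).
    """

    breaths_per_min: float = 17.0
    insp_frac: float = 0.4
    base_noise_band_hz: tuple[float, float] = (100.0, 1800.0)
    amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.insp_frac < 1.0:
            raise ValueError("insp_frac must lie in (0, 1)")
        if self.breaths_per_min <= 0:
            raise ValueError("breaths_per_min must be positive")
        lo, hi = self.base_noise_band_hz
        if not 0 < lo < hi:
            raise ValueError("base_noise_band_hz must satisfy 0 < low < high")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.breaths_per_min


@dataclass(frozen=True)
class LabeledRecording:
    """A mono waveform with its class label and generation metadata."""

    samples: np.ndarray = field(repr=False)
    sample_rate_hz: int
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a nonempty 1-D array")
        if np.max(np.abs(s)) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", s)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def as_waveform(self) -> Waveform:
        return Waveform(np.asarray(self.samples, dtype=np.float64), self.sample_rate_hz)


def _default_counts() -> dict[str, int]:
    return {"normal": 1222, "crackle": 297, "wheeze": 298, "rhonchus": 101}


@dataclass(frozen=True)
class SynthDatasetConfig:
    """Composition and acoustics of a generated corpus.

    Default class counts reproduce the study composition of the emulated
    database: 1222 normal, 297 crackle, 298 wheeze, 101 rhonchus (1918 total).
    """

    counts: dict[str, int] = field(default_factory=_default_counts)
    sample_rate_hz: int = 8000
    recording_duration_s: tuple[float, float] = (10.0, 20.0)
    events_per_recording: tuple[int, int] = (3, 8)
    snr_db: float = 10.0
    contaminant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {lab: 0 for lab in LABELS}
        for lab, n in self.counts.items():
            if lab not in LABELS:
                raise ValueError(f"unknown class {lab!r} in counts")
            if n < 0:
                raise ValueError("counts must be nonnegative")
            counts[lab] = int(n)
        object.__setattr__(self, "counts", counts)
        lo, hi = self.recording_duration_s
        if not 0 < lo <= hi:
            raise ValueError("recording_duration_s must be an increasing positive range")
        if lo < 60.0 / 15.0:  # one full cycle at the slowest default rate
            raise ValueError("recordings must span at least one breath cycle (4 s)")
        if self.sample_rate_hz < 2 * 1800:
            raise ValueError("sample_rate_hz must support the base noise band")
        if not 0.0 <= self.contaminant_prob <= 1.0:
            raise ValueError("contaminant_prob must lie in [0, 1]")
        e_lo, e_hi = self.events_per_recording
        if not 1 <= e_lo <= e_hi:
            raise ValueError("events_per_recording must be an increasing range >= 1")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# measurement utilities (shared by generator internals and tests)
# ---------------------------------------------------------------------------

def effective_duration(x: np.ndarray, rate_hz: int, frac: float = 0.99) -> float:
    """Span (s) from onset to the ``frac``-cumulative-energy point."""
    e = np.cumsum(np.square(np.asarray(x, dtype=np.float64)))
    if e[-1] == 0:
        return 0.0
    idx = int(np.searchsorted(e, frac * e[-1]))
    return (idx + 1) / rate_hz


def dominant_frequency(x: np.ndarray, rate_hz: int, pad_factor: int = 8) -> float:
    """Frequency (Hz) of the magnitude-spectrum maximum, zero-padded."""
    x = np.asarray(x, dtype=np.float64)
    n = int(2 ** np.ceil(np.log2(x.size * pad_factor)))
    mag = np.abs(np.fft.rfft(x, n=n))
    mag[0] = 0.0  # ignore DC
    return float(np.fft.rfftfreq(n, d=1.0 / rate_hz)[np.argmax(mag)])


def spectral_flatness(x: np.ndarray) -> float:
    """Geometric/arithmetic mean ratio of the power spectrum (0=tonal, 1=noise)."""
    p = np.square(np.abs(np.fft.rfft(np.asarray(x, dtype=np.float64))))
    p = p[1:]  # drop DC
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


# ---------------------------------------------------------------------------
# breath-cycle base
# ---------------------------------------------------------------------------

def breath_envelope(t: np.ndarray, params: BreathCycleParams) -> np.ndarray:
    """Amplitude envelope of the respiratory cycle at times ``t`` (s).

    Inspiration occupies the first ``insp_frac`` of each cycle as a full-height
    half-sine bump; expiration is a lower (0.7x) bump; a small floor keeps the
    base audible throughout.
    """
    phase = np.mod(np.asarray(t, dtype=np.float64) / params.cycle_s, 1.0)
    insp = phase < params.insp_frac
    env = np.empty_like(phase)
    env[insp] = np.sin(np.pi * phase[insp] / params.insp_frac)
    env[~insp] = 0.7 * np.sin(
        np.pi * (phase[~insp] - params.insp_frac) / (1.0 - params.insp_frac)
    )
    return 0.05 + 0.95 * np.abs(env)


def _pink_band_noise(
    n: int, rate_hz: int, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Band-limited noise with 1/f power weighting inside ``band``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    lo, hi = band
    w = np.zeros_like(f)
    inside = (f >= lo) & (f <= hi)
    w[inside] = 1.0 / np.sqrt(np.maximum(f[inside], lo))
    # raised-cosine skirts over 10% of the band edges to avoid ringing
    for edge, sgn in ((lo, 1.0), (hi, -1.0)):
        width = 0.1 * (hi - lo)
        zone = np.abs(f - edge) < width
        ramp = 0.5 * (1 + sgn * np.sin(np.pi * (f[zone] - edge) / (2 * width)))
        w[zone] = ramp / np.sqrt(np.maximum(f[zone], lo))
    x = np.fft.irfft(spec * w, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_breath_base(
    params: BreathCycleParams, duration_s: float, rate_hz: int, seed=0
) -> LabeledRecording:
    """Normal breath-sound base: pink-weighted band noise under the cycle envelope."""
    if duration_s < params.cycle_s:
        raise ValueError(
            f"duration {duration_s:.2f} s is shorter than one breath cycle "
            f"({params.cycle_s:.2f} s)"
        )
    if params.base_noise_band_hz[1] >= rate_hz / 2:
        raise ValueError("base noise band extends to or beyond Nyquist")
    rng = _rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    if params.amplitude == 0:
        x = np.zeros(n)
    else:
        noise = _pink_band_noise(n, rate_hz, params.base_noise_band_hz, rng)
        x = noise * breath_envelope(t, params)
        peak = np.max(np.abs(x))
        if peak > 0:
            x *= params.amplitude / peak
    return LabeledRecording(
        x,
        rate_hz,
        "normal",
        meta={"cycle_params": dataclasses.asdict(params), "events": []},
    )


# ---------------------------------------------------------------------------
# adventitious events
# ---------------------------------------------------------------------------

def synthesize_transient(
    profile: AcousticProfile, rate_hz: int, seed=0, freq_jitter: float = 0.03
) -> np.ndarray:
    """One crackle: an exponentially damped sinusoid.

    The damping constant is set so the 99%-cumulative-energy span equals the
    profile's nominal duration; the waveform is rendered for three nominal
    durations, by which point the envelope has decayed to 0.1% of its peak.
    """
    if profile.waveform_family != "damped_deflection":
        raise ValueError(f"{profile.class_name} is not a damped-deflection profile")
    f0 = float(profile.center_freq_hz)
    if f0 >= rate_hz / 2:
        raise ValueError(f"center frequency {f0} Hz is at or above Nyquist")
    rng = _rng(seed)
    f = f0 * (1.0 + freq_jitter * rng.uniform(-1, 1))
    dur = profile.duration_ms / 1000.0
    tau = dur / _E99
    n = max(int(round(3 * dur * rate_hz)), 8)
    t = np.arange(n) / rate_hz
    amp = 0.8 + 0.4 * rng.uniform()
    x = amp * np.exp(-t / tau) * np.sin(2 * np.pi * f * t)
    return x / np.max(np.abs(x))


def synthesize_continuous(
    profile: AcousticProfile,
    duration_ms: float | None = None,
    rate_hz: int = 8000,
    seed=0,
    freq_hz: float | None = None,
    harmonics: tuple[float, ...] = (1.0, 0.15, 0.05),
    mod_depth: float = 0.3,
) -> np.ndarray:
    """One continuous musical event (wheeze/rhonchus/stridor): a quasi-sinusoid.

    Fundamental + weak harmonics, slow (2-6 Hz) amplitude modulation and a
    tapered onset/offset. A range-valued profile frequency is sampled
    log-uniformly from its clinical sub-range unless ``freq_hz`` is given.
    """
    if profile.waveform_family != "sinusoid":
        raise ValueError(f"{profile.class_name} is not a sinusoid profile")
    rng = _rng(seed)
    if duration_ms is None:
        duration_ms = profile.duration_ms
    if duration_ms <= 80.0:
        warnings.warn(
            f"continuous {profile.class_name} of {duration_ms} ms violates the "
            ">80 ms duration convention for continuous sounds",
            stacklevel=2,
        )
    if freq_hz is None:
        cf = profile.center_freq_hz
        if isinstance(cf, tuple):
            lo = max(cf[0], WHEEZE_SAMPLING_RANGE_HZ[0])
            hi = min(cf[1], WHEEZE_SAMPLING_RANGE_HZ[1], 0.45 * rate_hz)
            freq_hz = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            freq_hz = float(cf) * (1.0 + 0.05 * rng.uniform(-1, 1))
    if freq_hz >= rate_hz / 2:
        raise ValueError(f"frequency {freq_hz} Hz is at or above Nyquist")
    n = max(int(round(duration_ms / 1000.0 * rate_hz)), 8)
    t = np.arange(n) / rate_hz
    x = np.zeros(n)
    for k, a in enumerate(harmonics, start=1):
        fk = k * freq_hz
        if fk >= rate_hz / 2 or a == 0:
            continue
        x += a * np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi) * (k > 1))
    if mod_depth > 0:
        fm = rng.uniform(2.0, 6.0)
        x *= 1.0 + mod_depth * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
    # tapered edges (10% each side)
    edge = max(int(0.1 * n), 1)
    taper = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    taper[:edge] = ramp
    taper[-edge:] = ramp[::-1]
    x *= taper
    return x / np.max(np.abs(x))


def _pleural_rub(profile: AcousticProfile, rate_hz: int, rng) -> np.ndarray:
    """Rhythmic succession of short low-frequency thumps (distractor only)."""
    n = int(round(profile.duration_ms / 1000.0 * rate_hz))
    x = np.zeros(n)
    step = int(0.06 * rate_hz)
    thump_profile = PROFILES["coarse_crackle"]
    for start in range(0, n - step, step):
        th = synthesize_transient(
            dataclasses.replace(thump_profile, center_freq_hz=profile.center_freq_hz),
            rate_hz,
            rng,
        )
        stop = min(start + th.size, n)
        x[start:stop] += th[: stop - start]
    m = np.max(np.abs(x))
    return x / m if m > 0 else x


def synthesize_event(profile_name: str, rate_hz: int, seed=0) -> np.ndarray:
    """Dispatch on the profile's waveform family."""
    profile = PROFILES[profile_name]
    rng = _rng(seed)
    if profile.waveform_family == "damped_deflection":
        return synthesize_transient(profile, rate_hz, rng)
    if profile.waveform_family == "sinusoid":
        return synthesize_continuous(profile, rate_hz=rate_hz, seed=rng)
    return _pleural_rub(profile, rate_hz, rng)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _phase_windows(
    n: int, rate_hz: int, params: BreathCycleParams, policy: str, rng
) -> tuple[float, float]:
    """Pick one (start_s, end_s) placement window consistent with ``policy``."""
    cycle = params.cycle_s
    n_cycles = max(int(n / rate_hz / cycle), 1)
    c = int(rng.integers(0, n_cycles))
    insp = (c * cycle, (c + params.insp_frac) * cycle)
    exp = ((c + params.insp_frac) * cycle, (c + 1) * cycle)
    if policy == "inspiratory":
        return insp
    if policy == "expiratory_dominant":
        return exp if rng.uniform() < 0.8 else insp
    return insp if rng.uniform() < 0.5 else exp


def compose_recording(
    base: LabeledRecording,
    events: list[tuple[np.ndarray, str]],
    snr_db: float,
    seed=0,
    label: str | None = None,
) -> LabeledRecording:
    """Superimpose events on a breath base at phase-consistent onsets.

    Each event is scaled so that its power over its active span stands
    ``snr_db`` dB above the base power over the same span, then added at an
    onset drawn inside an inspiratory window (crackles, stridor) or a
    predominantly expiratory window (wheeze, rhonchus). Onsets are recorded in
    ``meta['events']``; the output is renormalized into [-1, 1] if needed.
    """
    if label is not None and label != "normal" and not events:
        raise ValueError(f"label {label!r} requires at least one event")
    rng = _rng(seed)
    x = np.asarray(base.samples, dtype=np.float64).copy()
    rate = base.sample_rate_hz
    params = BreathCycleParams(**base.meta["cycle_params"])
    ev_meta: list[dict] = []
    classes = set()
    for wave, cls in events:
        wave = np.asarray(wave, dtype=np.float64)
        if cls not in PROFILES:
            raise ValueError(f"unknown event class {cls!r}")
        classes.add(cls)
        policy = PROFILES[cls].phase_bias
        span_s = wave.size / rate
        w0, w1 = _phase_windows(x.size, rate, params, policy, rng)
        latest = min(w1 - span_s, x.size / rate - span_s)
        onset_s = w0 if latest <= w0 else float(rng.uniform(w0, latest))
        i0 = int(round(onset_s * rate))
        i1 = min(i0 + wave.size, x.size)
        seg = wave[: i1 - i0]
        p_ev = np.mean(np.square(seg))
        p_base = np.mean(np.square(x[i0:i1]))
        if np.isneginf(snr_db) or p_ev == 0:
            scale = 0.0
        elif p_base == 0:
            scale = 1.0
        else:
            scale = np.sqrt(10.0 ** (snr_db / 10.0) * p_base / p_ev)
        x[i0:i1] += scale * seg
        ev_meta.append(
            {"onset_s": i0 / rate, "class": cls, "duration_s": span_s}
        )
    peak = np.max(np.abs(x))
    norm = 1.0 / peak if peak > 1.0 else 1.0
    x *= norm
    out_label = label
    if out_label is None:
        labelled = {_EVENT_LABEL[c] for c in classes if c in _EVENT_LABEL}
        out_label = labelled.pop() if len(labelled) == 1 else "normal"
    meta = dict(base.meta)
    meta.update(events=ev_meta, renorm=norm, snr_db=snr_db)
    return LabeledRecording(x, rate, out_label, meta=meta)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _make_one_recording(
    label: str, config: SynthDatasetConfig, rng: np.random.Generator
) -> LabeledRecording:
    rate = config.sample_rate_hz
    dur = float(rng.uniform(*config.recording_duration_s))
    params = BreathCycleParams(breaths_per_min=float(rng.uniform(15.0, 20.0)))
    base = synthesize_breath_base(params, dur, rate, rng)
    if label == "normal":
        rec = base
    else:
        n_ev = int(rng.integers(config.events_per_recording[0],
                                config.events_per_recording[1] + 1))
        if label == "crackle":
            profile_name = "fine_crackle" if rng.uniform() < 0.5 else "coarse_crackle"
        else:
            profile_name = label
        events = [(synthesize_event(profile_name, rate, rng), profile_name)
                  for _ in range(n_ev)]
        rec = compose_recording(base, events, config.snr_db, rng, label=label)
    if config.contaminant_prob > 0 and rng.uniform() < config.contaminant_prob:
        kind = _CONTAMINANT_KINDS[int(rng.integers(0, len(_CONTAMINANT_KINDS)))]
        rec = add_contaminants(rec, [kind], level_db=-5.0, seed=rng)
    return LabeledRecording(
        rec.samples.astype(np.float32), rate, rec.label, meta=rec.meta
    )


def generate_dataset(
    config: SynthDatasetConfig,
) -> tuple[list[LabeledRecording], pd.DataFrame]:
    """Generate the full labeled corpus plus a per-recording manifest.

    Deterministic given ``config.seed``: each recording draws from its own
    seed-sequence child, so the corpus is reproducible recording-by-recording.
    """
    ss = np.random.SeedSequence(config.seed)
    total = sum(config.counts.values())
    children = ss.spawn(total) if total else []
    recordings: list[LabeledRecording] = []
    rows = []
    i = 0
    for label in LABELS:
        for k in range(config.counts[label]):
            rng = np.random.default_rng(children[i])
            rec = _make_one_recording(label, config, rng)
            rec_id = f"{label}_{k:04d}"
            rec.meta["id"] = rec_id
            recordings.append(rec)
            times = ";".join(
                f"{e['onset_s']:.3f}" for e in rec.meta.get("events", [])
            )
            rows.append(
                {
                    "id": rec_id,
                    "label": label,
                    "duration_s": round(rec.duration_s, 6),
                    "sample_rate": rec.sample_rate_hz,
                    "n_events": len(rec.meta.get("events", [])),
                    "event_times": times,
                }
            )
            i += 1
    manifest = pd.DataFrame(
        rows,
        columns=["id", "label", "duration_s", "sample_rate", "n_events", "event_times"],
    )
    return recordings, manifest


def save_dataset(
    recordings: list[LabeledRecording], manifest: pd.DataFrame, out_dir
) -> None:
    """Write PCM-16 WAVs (one per recording) and the CSV manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_wav(rec.as_waveform(), out / f"{rec.meta['id']}.wav")
    manifest.to_csv(out / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# contaminants
# ---------------------------------------------------------------------------

def _contaminant_wave(
    kind: str, n: int, rate_hz: int, rng, heart_rate_hz: float
) -> np.ndarray:
    t = np.arange(n) / rate_hz
    x = np.zeros(n)
    if kind == "heart_sound":
        period = int(rate_hz / heart_rate_hz)
        thump_len = int(0.08 * rate_hz)
        tt = np.arange(thump_len) / rate_hz
        thump = np.exp(-tt / 0.02) * np.sin(2 * np.pi * 45.0 * tt)
        for start in range(0, n - thump_len, period):
            x[start : start + thump_len] += thump
    elif kind == "cough":
        start = int(rng.uniform(0, max(n - int(0.3 * rate_hz), 1)))
        m = min(int(0.3 * rate_hz), n - start)
        burst = _pink_band_noise(m, rate_hz, (300.0, min(2000.0, rate_hz / 2 - 1)), rng)
        env = np.exp(-np.arange(m) / (0.08 * rate_hz))
        x[start : start + m] += burst * env
    elif kind == "voice_like":
        start = int(rng.uniform(0, max(n - int(0.4 * rate_hz), 1)))
        m = min(int(0.4 * rate_hz), n - start)
        tt = np.arange(m) / rate_hz
        f0 = rng.uniform(100.0, 220.0)
        v = sum(
            (0.8**k) * np.sin(2 * np.pi * k * f0 * tt) for k in range(1, 6)
        )
        v *= 1 + 0.5 * np.sin(2 * np.pi * 3.0 * tt)
        x[start : start + m] += v
    elif kind == "alarm":
        beep_len = int(0.1 * rate_hz)
        period = int(0.5 * rate_hz)
        tt = np.arange(beep_len) / rate_hz
        beep = np.sin(2 * np.pi * 1000.0 * tt) * np.hanning(beep_len)
        for start in range(0, n - beep_len, period):
            x[start : start + beep_len] += beep
    else:
        raise ValueError(
            f"unknown contaminant kind {kind!r}; valid: {_CONTAMINANT_KINDS}"
        )
    return x


def add_contaminants(
    rec: LabeledRecording,
    kinds,
    level_db: float,
    seed=0,
    heart_rate_hz: float = 1.0,
) -> LabeledRecording:
    """Add ward-noise interference (cough/voice/heart/alarm) at ``level_db``
    relative to the recording's power. The label is unchanged."""
    rng = _rng(seed)
    kinds = list(kinds)
    for kind in kinds:
        if kind not in _CONTAMINANT_KINDS:
            raise ValueError(
                f"unknown contaminant kind {kind!r}; valid: {_CONTAMINANT_KINDS}"
            )
    if not kinds:
        return rec
    x = np.asarray(rec.samples, dtype=np.float64).copy()
    p_rec = np.mean(np.square(x))
    contam_meta = list(rec.meta.get("contaminants", []))
    for kind in kinds:
        c = _contaminant_wave(kind, x.size, rec.sample_rate_hz, rng, heart_rate_hz)
        p_c = np.mean(np.square(c))
        if p_c > 0 and p_rec > 0:
            c *= np.sqrt(10.0 ** (level_db / 10.0) * p_rec / p_c)
        x += c
        active = np.flatnonzero(np.abs(c) > 1e-12)
        t0 = float(active[0] / rec.sample_rate_hz) if active.size else 0.0
        contam_meta.append({"kind": kind, "level_db": level_db, "start_s": t0})
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x /= peak
    meta = dict(rec.meta)
    meta["contaminants"] = contam_meta
    return LabeledRecording(x, rec.sample_rate_hz, rec.label, meta=meta)
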