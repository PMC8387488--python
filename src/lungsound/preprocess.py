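"""Segmentation and three-channel log-Mel spectrogram stacks.

A recording is cut into 6-s windows with 50% overlap (hop 3 s); each window
becomes a 3x256x256 image stack:

1. log-Mel spectrogram,
2. log of the average of the harmonic and percussive Mel spectrograms
   (median-filter HPSS with soft masks that sum to one per bin),
3. time-derivative (delta) of the log-Mel spectrogram.

Six seconds covers two to three respiratory cycles at the normal 15-20
breaths/min rate, which is the minimum context needed to judge a lung sound.

Defaults (n_mels=128, n_fft=1024, hop_length=256 at 8 kHz) put the native Mel
image within a factor of two of the 256x256 target on both axes before the
bilinear resize. The STFT uses centered, reflection-padded framing with a Hann
window; Mel filters are triangular on the HTK Mel scale; log uses a 1e-10
power floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from skimage.transform import resize

from .audio_io import Waveform

__all__ = [
    "Segment",
    "SpectrogramStack",
    "PreprocessConfig",
    "TooShortError",
    "segment",
    "stft_power",
    "mel_filterbank",
    "mel_spectrogram",
    "hpss_masks",
    "hpss_average",
    "mel_delta",
    "build_stack",
]

CHANNEL_SEMANTICS = ("log_mel", "log_mel_hpss_avg", "mel_delta")


class TooShortError(ValueError):
    """Recording too short to yield even one padded analysis window."""


@dataclass(frozen=True)
class Segment:
    samples: np.ndarray = field(repr=False)
    sample_rate_hz: int = 8000
    parent_id: str = ""
    offset_s: float = 0.0


@dataclass(frozen=True)
class SpectrogramStack:
    """The 3x256x256 image stack fed to a feature extractor."""

    channels: np.ndarray = field(repr=False)  # (3, 256, 256) float32
    channel_semantics: tuple = CHANNEL_SEMANTICS
    norm_params: dict = field(default_factory=dict)
    segment_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.channels)
        if c.shape != (3, 256, 256):
            raise ValueError(f"stack must be 3x256x256, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("stack contains non-finite values")


@dataclass(frozen=True)
class PreprocessConfig:
    window_s: float = 6.0
    overlap_frac: float = 0.5
    n_mels: int = 128
    n_fft: int = 1024
    hop_length: int = 256
    log_floor: float = 1e-10
    out_size: int = 256
    hpss_kernel: int = 31
    delta_width: int = 9


def segment(
    w: Waveform, window_s: float = 6.0, overlap_frac: float = 0.5, parent_id: str = ""
) -> list[Segment]:
    """Cut a recording into fully contained overlapping windows.

    hop = window * (1 - overlap); count = floor((T - window)/hop) + 1 for
    T >= window (trailing partial windows dropped). Recordings between half a
    window and one window are reflection-padded to a single window; anything
    shorter is rejected.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    rate = w.sample_rate_hz
    win = int(round(window_s * rate))
    hop = int(round(window_s * (1.0 - overlap_frac) * rate))
    n = w.samples.size
    if n < win / 2:
        raise TooShortError(
            f"recording {parent_id!r} is {n / rate:.2f} s; "
            f"need at least {window_s / 2:.2f} s"
        )
    if n < win:
        pad = np.pad(w.samples, (0, win - n), mode="reflect")
        return [Segment(pad, rate, parent_id, 0.0)]
    count = (n - win) // hop + 1
    return [
        Segment(w.samples[i * hop : i * hop + win], rate, parent_id, i * hop / rate)
        for i in range(count)
    ]


# ---------------------------------------------------------------------------
# spectrogram primitives
# ---------------------------------------------------------------------------

def stft_power(
    x: np.ndarray, n_fft: int, hop_length: int, magnitude: bool = False
) -> np.ndarray:
    """Centered Hann-window STFT; returns power (or magnitude) spectrogram
    of shape (n_fft//2 + 1, n_frames) with n_frames = len(x)//hop + 1."""
    x = np.asarray(x, dtype=np.float64)
    if n_fft > x.size:
        raise ValueError("n_fft exceeds the segment length")
    pad = n_fft // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    n_frames = x.size // hop_length + 1
    idx = hop_length * np.arange(n_frames)[:, None] + np.arange(n_fft)[None, :]
    frames = xp[idx] * np.hanning(n_fft)[None, :]
    spec = np.fft.rfft(frames, axis=1).T  # (freq, time)
    mag = np.abs(spec)
    return mag if magnitude else np.square(mag)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    rate_hz: int, n_fft: int, n_mels: int, fmin: float = 0.0, fmax: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filters (HTK scale). Returns (filters, center_freqs_hz)
    with filters of shape (n_mels, n_fft//2 + 1)."""
    if n_mels < 1 or n_fft < 4:
        raise ValueError("degenerate n_mels/n_fft")
    if fmax is None:
        fmax = rate_hz / 2.0
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate_hz)
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = edges_hz[m : m + 3]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb, edges_hz[1:-1]


def mel_spectrogram(
    seg: Segment | np.ndarray,
    rate_hz: int | None = None,
    n_mels: int = 128,
    n_fft: int = 1024,
    hop_length: int = 256,
    log: bool = True,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Log-scaled Mel-band power matrix of shape (n_mels, n_frames)."""
    if isinstance(seg, Segment):
        x, rate_hz = seg.samples, seg.sample_rate_hz
    else:
        x = np.asarray(seg)
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare array")
    power = stft_power(x, n_fft, hop_length)
    fb, _ = mel_filterbank(rate_hz, n_fft, n_mels)
    mel = fb @ power
    return np.log(mel + log_floor) if log else mel


def hpss_masks(mag: np.ndarray, kernel: int = 31, p: float = 2.0):
    """Median-filter harmonic/percussive soft masks; they sum to 1 per bin.

    Harmonic structure is horizontal (sustained across time), percussive
    vertical (broadband at one instant), so the harmonic estimate is a median
    along time and the percussive one a median along frequency.
    """
    h = median_filter(mag, size=(1, kernel), mode="reflect")
    p_ = median_filter(mag, size=(kernel, 1), mode="reflect")
    hp, pp = h**p, p_**p
    denom = hp + pp
    zero = denom == 0
    denom[zero] = 1.0
    mask_h = hp / denom
    mask_p = pp / denom
    mask_h[zero] = 0.5
    mask_p[zero] = 0.5
    return mask_h, mask_p


def hpss_average(
    seg: Segment | np.ndarray,
    rate_hz: int | None = None,
    n_mels: int = 128,
    n_fft: int = 1024,
    hop_length: int = 256,
    kernel: int = 31,
    log: bool = True,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Log of the mean of harmonic and percussive Mel power spectrograms."""
    if isinstance(seg, Segment):
        x, rate_hz = seg.samples, seg.sample_rate_hz
    else:
        x = np.asarray(seg)
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare array")
    mag = stft_power(x, n_fft, hop_length, magnitude=True)
    mask_h, mask_p = hpss_masks(mag, kernel=kernel)
    fb, _ = mel_filterbank(rate_hz, n_fft, n_mels)
    mel_h = fb @ np.square(mag * mask_h)
    mel_p = fb @ np.square(mag * mask_p)
    avg = 0.5 * (mel_h + mel_p)
    return np.log(avg + log_floor) if log else avg


def mel_delta(mel: np.ndarray, width: int = 9) -> np.ndarray:
    """Local-regression (Savitzky-Golay) time derivative of each Mel band."""
    mel = np.asarray(mel, dtype=np.float64)
    if mel.shape[1] < width:
        raise ValueError(
            f"need at least {width} frames for the delta window, got {mel.shape[1]}"
        )
    return savgol_filter(mel, window_length=width, polyorder=1, deriv=1, axis=1)


def _minmax01(a: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-12:
        return np.zeros_like(a), lo, hi
    return (a - lo) / (hi - lo), lo, hi


def build_stack(seg: Segment, config: PreprocessConfig | None = None) -> SpectrogramStack:
    """Compute the three channels, resize each to 256x256 (bilinear), and
    min-max normalize each channel to [0, 1] per segment."""
    cfg = config or PreprocessConfig()
    kw = dict(n_mels=cfg.n_mels, n_fft=cfg.n_fft, hop_length=cfg.hop_length)
    log_mel = mel_spectrogram(seg, log_floor=cfg.log_floor, **kw)
    hpss = hpss_average(seg, kernel=cfg.hpss_kernel, log_floor=cfg.log_floor, **kw)
    delta = mel_delta(log_mel, width=cfg.delta_width)
    chans, norms = [], []
    for raw in (log_mel, hpss, delta):
        img = resize(
            raw,
            (cfg.out_size, cfg.out_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        scaled, lo, hi = _minmax01(img)
        chans.append(scaled.astype(np.float32))
        norms.append({"min": lo, "max": hi})
    seg_id = f"{seg.parent_id}@{seg.offset_s:.1f}" if seg.parent_id else ""
    return SpectrogramStack(
        np.stack(chans),
        CHANNEL_SEMANTICS,
        {"per_channel": norms},
        segment_id=seg_id,
    )
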