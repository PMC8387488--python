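"""WAV reading/writing and the pipeline's canonical waveform representation.

Every downstream stage consumes a :class:`Waveform`: mono, float, samples in
[-1, 1]. Multichannel input is reduced to mono by the arithmetic channel
mean; integer PCM is rescaled by the full-scale value of its dtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["Waveform", "AudioFormatError", "read_wav", "write_wav", "resample"]


class AudioFormatError(ValueError):
    """Raised for unreadable, empty, or unsupported audio files."""


# full-scale divisors for integer PCM dialects
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # offset binary: (x - 128) / 128
}


@dataclass(frozen=True)
class Waveform:
    """Mono audio in the canonical float representation.

    Parameters
    ----------
    samples : ndarray
        1-D float array with values in [-1, 1], finite.
    sample_rate_hz : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate_hz: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a nonempty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


def read_wav(path) -> Waveform:
    """Read a RIFF/WAVE file into the canonical mono float form.

    Integer PCM (8/16/32-bit) is scaled to [-1, 1]; float files are taken
    as-is. Channels are averaged to mono.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on corrupt input
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path!r} contains no samples")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        offset = 128.0 if data.dtype == np.uint8 else 0.0
        x = (data.astype(np.float64) - offset) / scale
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(
            f"unsupported WAV encoding {data.dtype} in {path!r}"
        )
    if x.ndim == 2:
        x = x.mean(axis=1)
    x = np.clip(x, -1.0, 1.0)
    return Waveform(x, int(rate))


def write_wav(w: Waveform, path, dtype: str = "pcm16") -> None:
    """Write a waveform as PCM-16 or float-32 WAV.

    Rejects clipped input (|x| > 1) rather than silently wrapping.
    """
    if np.max(np.abs(w.samples), initial=0.0) > 1.0:
        raise ValueError("waveform exceeds [-1, 1]; normalize before writing")
    if dtype == "pcm16":
        # symmetric full-scale so read_wav's /32768 inverts within one step
        q = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, w.sample_rate_hz, q)
    elif dtype == "float32":
        wavfile.write(path, w.sample_rate_hz, w.samples.astype(np.float32))
    else:
        raise ValueError(f"unknown WAV dtype {dtype!r}; use 'pcm16' or 'float32'")


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited polyphase resampling to ``target_rate``.

    Identity (same object contents) when the rates already match. Output
    length is ``round(n * target/source)`` up to the polyphase convention.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.sample_rate_hz:
        return Waveform(w.samples.copy(), w.sample_rate_hz)
    g = math.gcd(target_rate, w.sample_rate_hz)
    up, down = target_rate // g, w.sample_rate_hz // g
    y = resample_poly(w.samples, up, down)
    y = np.clip(y, -1.0, 1.0)
    return Waveform(y, target_rate)
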