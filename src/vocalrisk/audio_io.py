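"""Reading and standardizing sustained-vowel recordings.

The standardization pipeline mirrors common clinical-voice preprocessing:
mono mixdown, resampling to 16 kHz, a 4th-order Butterworth high-pass at
70 Hz (applied forward-backward, so cycle landmarks are not phase-shifted;
the nominal 8 kHz upper band edge coincides with Nyquist at 16 kHz and is
subsumed by the resampler's anti-alias filter), extraction of a central
clip of at least 0.5 s, and amplitude normalization to a fixed level
(peak -1 dBFS or RMS -20 dBFS).

Short-time analysis uses 25 ms Hamming windows with a 10 ms hop
(400/160 samples at 16 kHz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import AudioFormatError, NormalizationError, TooShortError

TARGET_RATE = 16_000
WINDOW_LENGTH = 400   # 25 ms at 16 kHz
HOP = 160             # 10 ms at 16 kHz
HIGHPASS_HZ = 70.0
PEAK_TARGET = 10.0 ** (-1.0 / 20.0)    # -1 dBFS
RMS_TARGET = 10.0 ** (-20.0 / 20.0)    # -20 dBFS

_INT_SCALES = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass
class AudioRecording:
    """Decoded audio with samples scaled to [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_path: str = ""

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sample_rate


@dataclass
class PhonationClip:
    """A standardized sustained-vowel segment at 16 kHz."""

    samples: np.ndarray
    clip_id: str = ""
    patient_id: str = ""
    sample_rate: int = TARGET_RATE

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sample_rate


@dataclass
class FrameSeries:
    """Hamming-windowed short-time frames of a clip.

    Frame k covers samples [k*hop, k*hop + window_length); raw (unwindowed)
    frames are kept alongside because autocorrelation-based measures need
    to correct for the window taper.
    """

    frames: np.ndarray            # (n_frames, window_length), windowed
    window_length: int = WINDOW_LENGTH
    hop: int = HOP
    sample_rate: int = TARGET_RATE
    window: np.ndarray = field(default_factory=lambda: np.hamming(WINDOW_LENGTH))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times(self) -> np.ndarray:
        """Start time of each frame in seconds (t_k = 0.010 * k)."""
        return np.arange(self.n_frames) * (self.hop / self.sample_rate)


def load_audio(path: str | Path) -> AudioRecording:
    """Read a RIFF/WAVE PCM file and scale samples to [-1, 1].

    Integer PCM is divided by the full-scale magnitude (e.g. 32768 for
    16-bit), so a full-scale 16-bit square wave decodes to +/-32767/32768.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises ValueError on malformed files
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"empty WAV file: {path}")
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.dtype(np.float32), np.dtype(np.float64)):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    return AudioRecording(samples=samples, sample_rate=int(rate), source_path=str(path))


def write_clip(clip: PhonationClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV at its sample rate."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate,
                  np.round(x * 32767.0).astype(np.int16))


def _to_mono(samples: np.ndarray) -> np.ndarray:
    if samples.ndim == 1:
        return samples
    return samples.mean(axis=1)


def _resample(samples: np.ndarray, rate: int, target: int = TARGET_RATE) -> np.ndarray:
    if rate == target:
        return samples
    frac = Fraction(target, rate)
    return sps.resample_poly(samples, frac.numerator, frac.denominator)


def highpass(samples: np.ndarray, rate: int = TARGET_RATE,
             cutoff_hz: float = HIGHPASS_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass."""
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, samples)


def normalize(samples: np.ndarray, norm_mode: str = "peak") -> np.ndarray:
    """Scale to peak -1 dBFS or RMS -20 dBFS."""
    if norm_mode == "peak":
        level = np.max(np.abs(samples))
        target = PEAK_TARGET
    elif norm_mode == "rms":
        level = math.sqrt(float(np.mean(samples ** 2)))
        target = RMS_TARGET
    else:
        raise ValueError(f"norm_mode must be 'peak' or 'rms', got {norm_mode!r}")
    if level <= 0.0 or not np.isfinite(level):
        raise NormalizationError("normalization undefined for all-zero signal")
    return samples * (target / level)


def standardize(rec: AudioRecording, norm_mode: str = "peak") -> AudioRecording:
    """Mono mixdown -> resample to 16 kHz -> 70 Hz high-pass -> normalize."""
    if rec.samples.size == 0:
        raise AudioFormatError("empty recording")
    x = _to_mono(np.asarray(rec.samples, dtype=np.float64))
    x = _resample(x, rec.sample_rate)
    x = highpass(x)
    x = normalize(x, norm_mode)
    return AudioRecording(samples=x, sample_rate=TARGET_RATE, source_path=rec.source_path)


def extract_central_clip(rec: AudioRecording, min_duration_s: float = 0.5,
                         clip_seconds: float = 1.0, clip_id: str = "",
                         patient_id: str = "") -> PhonationClip:
    """Take the centered segment of length max(min_duration_s, clip_seconds).

    A recording shorter than the target clip length but at least
    ``min_duration_s`` long is returned whole; anything shorter raises
    :class:`TooShortError`.
    """
    n = rec.samples.shape[0]
    fs = rec.sample_rate
    dur = n / fs
    if dur < min_duration_s - 1e-9:
        raise TooShortError(
            f"recording lasts {dur:.3f} s, below minimum {min_duration_s:.3f} s",
            duration_s=dur,
        )
    target = int(round(max(min_duration_s, clip_seconds) * fs))
    take = min(target, n)
    start = (n - take) // 2
    return PhonationClip(samples=rec.samples[start:start + take],
                         clip_id=clip_id, patient_id=patient_id, sample_rate=fs)


def frame_signal(clip: PhonationClip, window_length: int = WINDOW_LENGTH,
                 hop: int = HOP) -> FrameSeries:
    """Slice a clip into Hamming-windowed frames.

    Frame count is floor((N - window_length)/hop) + 1; frame k starts at
    sample k*hop.
    """
    x = np.asarray(clip.samples, dtype=np.float64)
    n = x.shape[0]
    if n < window_length:
        raise TooShortError(
            f"clip has {n} samples, below one window ({window_length})",
            duration_s=n / clip.sample_rate,
        )
    n_frames = (n - window_length) // hop + 1
    idx = np.arange(window_length)[None, :] + hop * np.arange(n_frames)[:, None]
    window = np.hamming(window_length)
    return FrameSeries(frames=x[idx] * window, window_length=window_length,
                       hop=hop, sample_rate=clip.sample_rate, window=window)
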