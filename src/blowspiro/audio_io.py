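"""Reading, resampling, normalizing and validating exhalation recordings.

A forced-exhalation recording is a short (~5-10 s) mono waveform captured at
roughly 20 cm from the mouth.  Everything downstream works on a single
canonical representation: mono float samples in [-1, 1] at a known rate.
Because the microphone gain is uncontrolled, amplitude is normalized to peak
1.0 once at load; all decibel features are therefore level-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioFormatError

#: Canonical internal sample rate (Hz); all inputs are resampled to it before
#: feature extraction so the frequency-band edges keep a fixed meaning.
CANONICAL_RATE = 44_100

_INT_SCALES = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31,
               np.dtype(np.uint8): 2.0**7}


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform with its rate.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``sample_rate`` is in
    samples/second.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of basic exhalation-quality checks."""

    ok: bool
    duration_s: float
    clipped_fraction: float
    silence: bool
    messages: list[str] = field(default_factory=list)


def read_wav(path: str | Path, normalize: bool = True) -> AudioSignal:
    """Read a PCM WAV file as a mono :class:`AudioSignal`.

    Stereo is averaged to mono; integer formats are rescaled to [-1, 1].
    With ``normalize`` (the default) the waveform is peak-normalized to 1.0,
    which makes all reference-max decibel features independent of recording
    gain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"{path}: not a readable PCM WAV ({exc})") from exc
    dtype = data.dtype
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    else:
        data = data.astype(np.float64)
    scale = _INT_SCALES.get(dtype)
    if scale is not None:
        if dtype == np.dtype(np.uint8):  # unsigned 8-bit is offset binary
            data = (data - 128.0) / scale
        else:
            data = data / scale
    if normalize:
        peak = np.max(np.abs(data))
        if peak > 0:
            data = data / peak
    return AudioSignal(samples=data, sample_rate=float(rate))


def write_wav(path: str | Path, sig: AudioSignal, dtype: str = "int16") -> None:
    """Write a signal as PCM WAV (``int16`` or ``float32``)."""
    if dtype == "int16":
        clipped = np.clip(sig.samples, -1.0, 1.0)
        data = (clipped * (2.0**15 - 1)).astype(np.int16)
    elif dtype == "float32":
        data = sig.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    wavfile.write(Path(path), int(sig.sample_rate), data)


def resample(sig: AudioSignal, target_rate: float) -> AudioSignal:
    """Band-limited resampling to ``target_rate`` (polyphase)."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == sig.sample_rate:
        return sig
    ratio = Fraction(int(round(target_rate)), int(round(sig.sample_rate))).limit_denominator(1000)
    out = resample_poly(sig.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(samples=out, sample_rate=float(target_rate))


def validate_exhalation(
    sig: AudioSignal,
    min_s: float = 2.0,
    max_s: float = 15.0,
    clip_thresh: float = 0.01,
) -> ValidationReport:
    """Check that a recording plausibly contains a forced exhalation.

    Silence is declared when RMS < 1e-6; a sample counts as clipped when
    |sample| >= 0.999.  A report is always returned, never raised.
    """
    if min_s >= max_s:
        raise ValueError(f"min_s must be < max_s, got ({min_s}, {max_s})")
    duration = sig.duration
    rms = float(np.sqrt(np.mean(sig.samples**2)))
    silence = rms < 1e-6
    clipped_fraction = float(np.mean(np.abs(sig.samples) >= 0.999))
    messages: list[str] = []
    if silence:
        messages.append("signal is silent (RMS < 1e-6)")
    if not (min_s <= duration <= max_s):
        messages.append(f"duration {duration:.2f} s outside [{min_s}, {max_s}] s")
    if clipped_fraction >= clip_thresh:
        messages.append(f"clipped fraction {clipped_fraction:.3f} >= {clip_thresh}")
    ok = (min_s <= duration <= max_s) and not silence and clipped_fraction < clip_thresh
    return ValidationReport(ok=ok, duration_s=duration,
                            clipped_fraction=clipped_fraction, silence=silence,
                            messages=messages)
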