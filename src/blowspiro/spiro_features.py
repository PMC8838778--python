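"""Spirometer-like features from an STFT decibel spectrogram.

Three scalar features approximate the classic spirometric measures from
audio alone:

* ``total_dec``      — sum of |dB| over the whole spectrogram (proxy for FVC,
  the total exhaled volume);
* ``total_dec_1st_sec`` — the same sum restricted to the first second
  (proxy for FEV1);
* ``max_peak``       — the spectrogram's dynamic range in dB (proxy for PEF,
  the peak flow).

Decibels are referenced to the spectrogram maximum, so all three features
are invariant to recording gain; with that convention the literal maximum of
the dB matrix is always 0, hence the peak feature is defined as the range
between the loudest cell and the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .audio_io import AudioSignal
from .errors import DegenerateInputError


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude STFT in decibels relative to its own maximum.

    ``db`` is (frequency-bin x time-frame), max exactly 0, floored at
    ``-floor_db``.
    """

    db: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_fft: int
    hop: int


@dataclass(frozen=True)
class SpiroFeatures:
    total_dec: float
    total_dec_1st_sec: float
    max_peak: float


def stft_db(
    sig: AudioSignal, n_fft: int = 2048, hop: int = 512, floor_db: float = 80.0
) -> Spectrogram:
    """Hann-window magnitude STFT converted to reference-max decibels."""
    if n_fft < 16:
        raise ValueError("n_fft must be >= 16")
    if not 0 < hop <= n_fft:
        raise ValueError("hop must satisfy 0 < hop <= n_fft")
    if not np.any(sig.samples):
        raise DegenerateInputError("all-zero signal: dB reference level undefined")
    stft = ShortTimeFFT(hann(n_fft, sym=False), hop=hop, fs=sig.sample_rate,
                        scale_to="magnitude")
    mag = np.abs(stft.stft(sig.samples))
    ref = mag.max()
    db = 20.0 * np.log10(np.maximum(mag / ref, 10.0 ** (-floor_db / 20.0)))
    freqs = stft.f
    times = stft.t(sig.samples.size)
    return Spectrogram(db=db, freqs=freqs, times=times, n_fft=n_fft, hop=hop)


def _check(spec: Spectrogram) -> None:
    if spec.db.size == 0:
        raise ValueError("empty spectrogram")


def total_dec(spec: Spectrogram) -> float:
    """Sum of absolute decibel values over all frequencies and frames."""
    _check(spec)
    return float(np.sum(np.abs(spec.db)))


def total_dec_1st_sec(spec: Spectrogram) -> float:
    """Sum of absolute decibels over frames with center time in [0, 1) s."""
    _check(spec)
    mask = spec.times < 1.0
    return float(np.sum(np.abs(spec.db[:, mask])))


def max_peak(spec: Spectrogram) -> float:
    """Dynamic range of the spectrogram: max(dB) - min(dB)."""
    _check(spec)
    return float(spec.db.max() - spec.db.min())


def extract_spiro_features(
    sig: AudioSignal, n_fft: int = 2048, hop: int = 512, floor_db: float = 80.0
) -> SpiroFeatures:
    """All three spirometer-like features of one recording."""
    spec = stft_db(sig, n_fft=n_fft, hop=hop, floor_db=floor_db)
    return SpiroFeatures(
        total_dec=total_dec(spec),
        total_dec_1st_sec=total_dec_1st_sec(spec),
        max_peak=max_peak(spec),
    )
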