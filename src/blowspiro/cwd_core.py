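"""Wigner-Ville and Choi-Williams time-frequency distributions.

The Wigner distribution W(t, f) of a signal offers the best joint
time-frequency resolution among quadratic distributions but suffers from
oscillatory cross-terms between signal components.  The Choi-Williams
distribution suppresses them by multiplying the ambiguity function (the 2-D
Fourier dual of W over doppler theta and lag tau) with the exponential
kernel

    Phi(theta, tau) = exp(-(2 pi)^2 theta^2 tau^2 / sigma),

which is 1 on both axes (preserving the marginals) and decays away from
them (killing cross-terms, which live at off-axis ambiguity positions).
Small sigma means aggressive smoothing; sigma -> infinity recovers the raw
Wigner distribution.

Discretization
--------------
A frame of ``frame_len`` real samples is made analytic (Hilbert transform,
removing negative frequencies and hence frequency aliasing), then the
instantaneous autocorrelation K[n, m] = x_a[n+m] x_a*[n-m] is formed for
lags m in [-L/2, L/2) with L = frame_len/2, zero outside the frame.  A DFT
over the lag axis yields ``L`` frequency bins f_k = k * fs / frame_len
covering [0, Nyquist) — with the default 1024-sample frame, 512
positive-frequency bins.  The kernel is applied in the ambiguity domain
(DFT of K over time).

The matrix is normalized to unit sum.  The time and frequency marginal
densities are computed directly from the analytic signal — instantaneous
power |x_a(t)|^2 and periodogram |X_a(f)|^2 on the same frequency grid —
which are the Wigner distribution's theoretical marginals and, unlike
slices of the smoothed matrix, guaranteed non-negative (so the entropy and
information features downstream are always defined).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateInputError


@dataclass(frozen=True)
class CWDConfig:
    """Choi-Williams analysis parameters.

    sigma : kernel parameter (> 0); smaller = more cross-term suppression.
    frame_len : samples per analysis frame (power of two, <= 4096).
    frame_hop : hop between frames in samples.
    eps : density floor used inside logarithms downstream.
    max_frames : per-recording cap on analysed frames; frames are subsampled
        uniformly so across-frame feature means stay unbiased estimates.
    """

    sigma: float = 1.0
    frame_len: int = 1024
    frame_hop: int = 512
    eps: float = 2.0**-30
    max_frames: int | None = 16

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        n = self.frame_len
        if n < 16 or n > 4096 or (n & (n - 1)) != 0:
            raise ValueError("frame_len must be a power of two in [16, 4096]")
        if not 0 < self.eps <= 1e-6:
            raise ValueError("eps must be in (0, 1e-6]")


@dataclass(frozen=True)
class TFDistribution:
    """Normalized Choi-Williams matrix with its marginal densities.

    ``cwdn`` is (frequency-bin x time-sample), real, summing to 1 (small
    negatives can remain after smoothing); ``mtN``/``mfN`` are the unit-sum,
    non-negative time and frequency marginal densities.
    """

    cwdn: np.ndarray
    mtN: np.ndarray
    mfN: np.ndarray
    times: np.ndarray
    freqs: np.ndarray


def analytic_signal(frame: np.ndarray) -> np.ndarray:
    """Hilbert-transform analytic signal; the real part equals the input."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 16:
        raise ValueError("frame too short (need >= 16 samples)")
    return hilbert(frame)


def wigner_ville(frame: np.ndarray, sample_rate: float) -> np.ndarray:
    """Discrete Wigner-Ville distribution of the analytic signal.

    Returns a (frame_len/2 frequency-bin x frame_len time-sample) real
    matrix; frequencies f_k = k * fs / frame_len over [0, Nyquist).
    """
    xa = analytic_signal(frame)
    kern = _autocorr_kernel(xa)
    return np.real(np.fft.fft(kern, axis=0))


def _autocorr_kernel(xa: np.ndarray) -> np.ndarray:
    """Instantaneous autocorrelation K[m, n] = x_a[n+m] x_a*[n-m].

    Lag axis of length L = len(xa)//2 arranged in FFT order (m = 0..L/2-1,
    then m = -L/2..-1); out-of-frame products are zero.
    """
    n = xa.size
    L = n // 2
    m = np.arange(-L // 2, L // 2)
    rows = m % L
    idx = np.arange(n)
    i_plus = idx[None, :] + m[:, None]
    i_minus = idx[None, :] - m[:, None]
    valid = (i_plus >= 0) & (i_plus < n) & (i_minus >= 0) & (i_minus < n)
    prod = xa[np.clip(i_plus, 0, n - 1)] * np.conj(xa[np.clip(i_minus, 0, n - 1)])
    prod[~valid] = 0.0
    kern = np.zeros((L, n), dtype=np.complex128)
    kern[rows] = prod
    return kern


@lru_cache(maxsize=8)
def _cw_ambiguity_kernel(n_time: int, n_lag: int, sigma: float) -> np.ndarray:
    """Choi-Williams kernel sampled on the discrete ambiguity grid.

    theta is the normalized doppler frequency (cycles/sample) of the DFT
    over time; tau is the physical lag in samples (2m for lag index m).
    """
    theta = np.fft.fftfreq(n_time)  # cycles per sample
    m = np.fft.fftfreq(n_lag) * n_lag  # lag indices .. -2,-1,0,1,2 ..
    tau = 2.0 * m
    return np.exp(-((2.0 * np.pi) ** 2) * np.outer(tau**2, theta**2) / sigma)


def choi_williams(
    frame: np.ndarray, cfg: CWDConfig | None = None, sample_rate: float = 44_100.0
) -> TFDistribution:
    """Choi-Williams distribution of one frame, normalized to unit sum.

    The exponential kernel is applied in the ambiguity domain; marginals are
    the instantaneous power and periodogram of the analytic signal, each
    normalized to unit sum.
    """
    cfg = cfg or CWDConfig()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size != cfg.frame_len:
        raise ValueError(f"frame length {frame.size} != cfg.frame_len {cfg.frame_len}")
    if not np.any(frame):
        raise DegenerateInputError("all-zero frame")
    xa = analytic_signal(frame)
    kern = _autocorr_kernel(xa)  # (lag, time)
    amb = np.fft.fft(kern, axis=1)  # -> (lag, doppler)
    amb *= _cw_ambiguity_kernel(kern.shape[1], kern.shape[0], cfg.sigma)
    smoothed = np.fft.ifft(amb, axis=1)  # back to (lag, time)
    cwd = np.real(np.fft.fft(smoothed, axis=0))  # (freq, time)
    total = cwd.sum()
    if total <= 0:
        raise DegenerateInputError("non-positive total energy after smoothing")
    cwdn = cwd / total

    n = frame.size
    n_f = n // 2
    mt = np.abs(xa) ** 2
    mtN = mt / mt.sum()
    # periodogram on the cwdn frequency grid: zero-padded FFT of length n,
    # bins k*fs/n for k < n/2
    spec = np.abs(np.fft.fft(xa, n=n)[:n_f]) ** 2
    mfN = spec / spec.sum()
    times = np.arange(n) / sample_rate
    freqs = np.arange(n_f) * sample_rate / n
    return TFDistribution(cwdn=cwdn, mtN=mtN, mfN=mfN, times=times, freqs=freqs)


def signal_marginals(
    samples: np.ndarray, sample_rate: float, n_t: int = 1024, n_f: int = 512
) -> TFDistribution:
    """Whole-recording marginal densities on a fixed grid.

    The time marginal is the instantaneous power of the analytic signal
    aggregated into ``n_t`` equal time cells; the frequency marginal is the
    periodogram aggregated into ``n_f`` bins of width fs / (2 n_f) covering
    [0, Nyquist).  Both are normalized to unit sum.  The fixed grid keeps
    the joint entropy H_t + H_f bounded by log2(n_t) + log2(n_f) bits
    regardless of recording length.

    Returned as a :class:`TFDistribution` with an empty ``cwdn`` (the 2-D
    smoothed matrix is frame-wise; see :func:`choi_williams`).
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = samples.size
    if n < n_t:
        raise ValueError(f"signal shorter than the {n_t}-cell time grid")
    if not np.any(samples):
        raise DegenerateInputError("all-zero signal")
    xa = hilbert(samples)
    power = np.abs(xa) ** 2
    cell = (np.arange(n) * n_t) // n
    mt = np.bincount(cell, weights=power, minlength=n_t)
    mtN = mt / mt.sum()

    spec = np.abs(np.fft.rfft(samples)) ** 2
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spacing = sample_rate / (2 * n_f)
    fbin = np.minimum((f // spacing).astype(int), n_f - 1)
    mf = np.bincount(fbin, weights=spec, minlength=n_f)
    mfN = mf / mf.sum()

    times = (np.arange(n_t) + 0.5) * n / (n_t * sample_rate)
    freqs = np.arange(n_f) * spacing
    return TFDistribution(cwdn=np.empty((0, 0)), mtN=mtN, mfN=mfN,
                          times=times, freqs=freqs)


def joint_density(tfd: TFDistribution) -> np.ndarray:
    """Separable joint density pD(f, t) = mfN(f) mtN(t); unit sum, >= 0."""
    return np.outer(tfd.mfN, tfd.mtN)


def frame_signal(samples: np.ndarray, cfg: CWDConfig) -> list[np.ndarray]:
    """Cut a signal into analysis frames, uniformly subsampled to
    ``cfg.max_frames``; frames that are entirely zero are skipped."""
    n = samples.size
    if n < cfg.frame_len:
        raise ValueError(f"signal shorter than one frame ({n} < {cfg.frame_len})")
    starts = np.arange(0, n - cfg.frame_len + 1, cfg.frame_hop)
    if cfg.max_frames is not None and starts.size > cfg.max_frames:
        pick = np.linspace(0, starts.size - 1, cfg.max_frames).round().astype(int)
        starts = starts[np.unique(pick)]
    frames = [samples[s:s + cfg.frame_len] for s in starts]
    return [f for f in frames if np.any(f)]
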