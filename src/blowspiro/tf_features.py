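"""The 38 time-frequency features of an exhalation recording.

28 features are computed per frequency band over seven fixed bands chosen
around the spectral location of a cold blow (0-80, 80-250, 250-550,
550-900, 900-1500, 1500-3000, 3000-Nyquist Hz):

* ``e_bn``    — mean instantaneous spectral energy in the band;
* ``f_cres``  — mean instantaneous frequency peak (in-band arg-max of the
  joint density);
* ``f_med``   — mean instantaneous frequency (energy-weighted in-band mean);
* ``ie_bn``   — mean spectral information -log2(mfN(f)) over band bins.

Ten more use the full frequency range: the time/frequency/joint Shannon
entropies H_t, H_f, H_tf = H_t + H_f; the kurtosis of the time marginal;
and six joint time-frequency moments t^n f^m of orders n = m in {1, 7, 15},
taken once over the signed Choi-Williams matrix (momC) and once over the
product of the marginal densities (momM), with both axes normalized to
[0, 1] so high orders stay in range.

Band features use the separable joint density pD(f,t) = mfN(f) mtN(t), so
every feature is invariant to the recording's amplitude scale.  Features
are computed per analysis frame and averaged across frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .audio_io import AudioSignal
from .cwd_core import (
    CWDConfig,
    TFDistribution,
    choi_williams,
    frame_signal,
    joint_density,
    signal_marginals,
)
from .errors import DegenerateInputError

#: Default band edges in Hz; the last edge is replaced by Nyquist at runtime.
DEFAULT_BAND_EDGES = (
    (0.0, 80.0), (80.0, 250.0), (250.0, 550.0), (550.0, 900.0),
    (900.0, 1500.0), (1500.0, 3000.0), (3000.0, None),
)

N_BANDS = 7
TF_FEATURE_NAMES = (
    [f"e_bn{i}" for i in range(1, 8)]
    + [f"f_cres{i}" for i in range(1, 8)]
    + [f"f_med{i}" for i in range(1, 8)]
    + [f"ie_bn{i}" for i in range(1, 8)]
    + ["h_t", "h_f", "h_tf", "k",
       "momc11", "momc77", "momc15", "momm11", "momm77", "momm15"]
)


@dataclass(frozen=True)
class BandSet:
    """Seven contiguous half-open [low, high) frequency bands covering
    [0, Nyquist]."""

    edges: tuple[tuple[float, float], ...]

    @classmethod
    def default(cls, nyquist: float = 22_050.0) -> "BandSet":
        edges = tuple(
            (lo, hi if hi is not None else nyquist) for lo, hi in DEFAULT_BAND_EDGES
        )
        return cls(edges=edges)

    def __post_init__(self) -> None:
        if len(self.edges) != N_BANDS:
            raise ValueError(f"expected {N_BANDS} bands, got {len(self.edges)}")
        for (lo1, hi1), (lo2, _) in zip(self.edges, self.edges[1:]):
            if hi1 != lo2 or lo1 >= hi1:
                raise ValueError("bands must be contiguous and non-overlapping")


@dataclass(frozen=True)
class TFFeatureVector:
    """The 38 time-frequency features; field order matches
    :data:`TF_FEATURE_NAMES`."""

    e_bn: tuple[float, ...]
    f_cres: tuple[float, ...]
    f_med: tuple[float, ...]
    ie_bn: tuple[float, ...]
    h_t: float
    h_f: float
    h_tf: float
    k: float
    momc11: float
    momc77: float
    momc15: float
    momm11: float
    momm77: float
    momm15: float

    def as_array(self) -> np.ndarray:
        vals: list[float] = []
        vals += list(self.e_bn) + list(self.f_cres) + list(self.f_med) + list(self.ie_bn)
        vals += [self.h_t, self.h_f, self.h_tf, self.k,
                 self.momc11, self.momc77, self.momc15,
                 self.momm11, self.momm77, self.momm15]
        return np.array(vals)


def _band_mask(freqs: np.ndarray, band: tuple[float, float], last: bool = False) -> np.ndarray:
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    if last:
        mask |= freqs == hi
    return mask


def band_energy(pD: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Instantaneous in-band spectral energy share E(t) and its time mean.

    E(t) is the in-band fraction of the spectrum at time t, i.e. the band
    slice of pD(f, t) normalized by the full-range column mass; the seven
    band features therefore partition to 1.  An empty band yields 0.
    """
    if band[0] < 0 or band[1] > freqs[-1] + (freqs[1] - freqs[0]):
        raise ValueError(f"band {band} outside frequency axis")
    mask = _band_mask(freqs, band)
    if not mask.any():
        return np.zeros(pD.shape[1]), 0.0
    col_mass = pD.sum(axis=0)
    e_t = np.divide(pD[mask, :].sum(axis=0), col_mass,
                    out=np.zeros(pD.shape[1]), where=col_mass > 0)
    return e_t, float(e_t.mean())


def band_freq_peak(
    pD: np.ndarray, freqs: np.ndarray, band: tuple[float, float], eps: float = 2.0**-30
) -> float:
    """Mean over time of the in-band arg-max frequency of pD(f, t).

    Time samples with no in-band energy above ``eps`` are excluded; an
    entirely silent band yields 0.  Ties break toward the lowest bin.
    """
    mask = _band_mask(freqs, band)
    if not mask.any():
        return 0.0
    sub = pD[mask, :]
    e_t = sub.sum(axis=0)
    keep = e_t > eps
    if not keep.any():
        return 0.0
    band_freqs = freqs[mask]
    peaks = band_freqs[np.argmax(sub[:, keep], axis=0)]
    return float(peaks.mean())


def band_freq_mean(
    pD: np.ndarray, freqs: np.ndarray, band: tuple[float, float], eps: float = 2.0**-30
) -> float:
    """Mean over time of the energy-weighted in-band mean frequency."""
    mask = _band_mask(freqs, band)
    if not mask.any():
        return 0.0
    sub = pD[mask, :]
    e_t = sub.sum(axis=0)
    keep = e_t > eps
    if not keep.any():
        return 0.0
    band_freqs = freqs[mask]
    fmi = (band_freqs[:, None] * sub[:, keep]).sum(axis=0) / e_t[keep]
    return float(fmi.mean())


def band_spectral_info(
    mfN: np.ndarray, freqs: np.ndarray, band: tuple[float, float], eps: float = 2.0**-30
) -> float:
    """Mean spectral information -log2(mfN) over the band's bins (bits)."""
    mask = _band_mask(freqs, band)
    if not mask.any():
        return 0.0
    return float(np.mean(-np.log2(np.maximum(mfN[mask], eps))))


def entropies(mtN: np.ndarray, mfN: np.ndarray) -> tuple[float, float, float]:
    """Shannon entropies (bits) of the marginals and their sum.

    H_t is the instantaneous entropy of the time marginal, H_f the spectral
    entropy, and H_tf = H_t + H_f the joint entropy of the product density.
    """
    for d in (mtN, mfN):
        if abs(d.sum() - 1.0) > 1e-6 or (d < 0).any():
            raise ValueError("marginals must be non-negative unit-sum densities")
    h_t = float(-np.sum(np.where(mtN > 0, mtN * np.log2(np.maximum(mtN, 1e-300)), 0.0)))
    h_f = float(-np.sum(np.where(mfN > 0, mfN * np.log2(np.maximum(mfN, 1e-300)), 0.0)))
    return h_t, h_f, h_t + h_f


def kurtosis(mtN: np.ndarray, times: np.ndarray | None = None) -> float:
    """Pearson kurtosis mu4/mu2^2 of time under the density mtN.

    Time is normalized to [0, 1]; a Gaussian density gives 3, a uniform one
    9/5 in the continuum limit.
    """
    n = mtN.size
    x = np.linspace(0.0, 1.0, n)
    mu = float(np.sum(x * mtN))
    mu2 = float(np.sum((x - mu) ** 2 * mtN))
    if mu2 <= 0:
        raise DegenerateInputError("zero variance: kurtosis undefined")
    mu4 = float(np.sum((x - mu) ** 4 * mtN))
    return mu4 / mu2**2


def joint_moments(
    cwdn: np.ndarray, mtN: np.ndarray, mfN: np.ndarray, orders: Iterable[int] = (1, 7, 15)
) -> tuple[float, ...]:
    """Joint time-frequency moments t^n f^n on [0, 1]-normalized axes.

    momC take the signed smoothed distribution; momM the product of the
    marginals (so momC == momM exactly when the distribution is separable).
    Returns (momc11, momc77, momc15, momm11, momm77, momm15).
    """
    n_f, n_t = cwdn.shape
    t_ax = np.linspace(0.0, 1.0, n_t)
    f_ax = np.linspace(0.0, 1.0, n_f)
    mom_c, mom_m = [], []
    for n in orders:
        tn, fn = t_ax**n, f_ax**n
        mom_c.append(float(fn @ cwdn @ tn))
        mom_m.append(float(np.sum(tn * mtN) * np.sum(fn * mfN)))
    return (*mom_c, *mom_m)


def features_from_tfd(tfd: TFDistribution, bands: BandSet, eps: float = 2.0**-30) -> TFFeatureVector:
    """The 38 features of a single frame's distribution."""
    pD = joint_density(tfd)
    freqs = tfd.freqs
    e_list, cres_list, med_list, ie_list = [], [], [], []
    for i, band in enumerate(bands.edges):
        _, e_mean = band_energy(pD, freqs, band)
        e_list.append(e_mean)
        cres_list.append(band_freq_peak(pD, freqs, band, eps))
        med_list.append(band_freq_mean(pD, freqs, band, eps))
        ie_list.append(band_spectral_info(tfd.mfN, freqs, band, eps))
    h_t, h_f, h_tf = entropies(tfd.mtN, tfd.mfN)
    k = kurtosis(tfd.mtN)
    moms = joint_moments(tfd.cwdn, tfd.mtN, tfd.mfN)
    return TFFeatureVector(
        e_bn=tuple(e_list), f_cres=tuple(cres_list), f_med=tuple(med_list),
        ie_bn=tuple(ie_list), h_t=h_t, h_f=h_f, h_tf=h_tf, k=k,
        momc11=moms[0], momc77=moms[1], momc15=moms[2],
        momm11=moms[3], momm77=moms[4], momm15=moms[5],
    )


def extract_tf_features(
    sig: AudioSignal, cfg: CWDConfig | None = None, bands: BandSet | None = None
) -> TFFeatureVector:
    """The 38 time-frequency features of one recording.

    Every marginal-based feature (band features, entropies, kurtosis, momM)
    is computed from the whole recording's marginal densities on the fixed
    1024-cell time x 512-bin frequency grid, so the exhalation's flow
    profile — the quantity the time marginal represents — enters the
    features directly.  Only the momC moments need the 2-D smoothed
    distribution; those are computed frame-wise and averaged across frames.
    Deterministic throughout.
    """
    cfg = cfg or CWDConfig()
    bands = bands or BandSet.default(nyquist=sig.sample_rate / 2.0)
    marg = signal_marginals(sig.samples, sig.sample_rate,
                            n_t=cfg.frame_len, n_f=cfg.frame_len // 2)
    pD = joint_density(marg)
    e_list, cres_list, med_list, ie_list = [], [], [], []
    for band in bands.edges:
        e_list.append(band_energy(pD, marg.freqs, band)[1])
        cres_list.append(band_freq_peak(pD, marg.freqs, band, cfg.eps))
        med_list.append(band_freq_mean(pD, marg.freqs, band, cfg.eps))
        ie_list.append(band_spectral_info(marg.mfN, marg.freqs, band, cfg.eps))
    h_t, h_f, h_tf = entropies(marg.mtN, marg.mfN)
    k = kurtosis(marg.mtN)
    _, _, _, momm11, momm77, momm15 = joint_moments(
        np.outer(marg.mfN, marg.mtN), marg.mtN, marg.mfN)

    frames = frame_signal(sig.samples, cfg)
    if not frames:
        raise DegenerateInputError("no non-zero frames in signal")
    momc = np.mean([
        joint_moments(
            (tfd := choi_williams(f, cfg, sig.sample_rate)).cwdn, tfd.mtN, tfd.mfN
        )[:3]
        for f in frames
    ], axis=0)
    return TFFeatureVector(
        e_bn=tuple(e_list), f_cres=tuple(cres_list), f_med=tuple(med_list),
        ie_bn=tuple(ie_list), h_t=h_t, h_f=h_f, h_tf=h_tf, k=k,
        momc11=float(momc[0]), momc77=float(momc[1]), momc15=float(momc[2]),
        momm11=momm11, momm77=momm77, momm15=momm15,
    )
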