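"""Synthetic forced-exhalation audio.

A blow sound is well approximated by white noise shaped by a band-pass
filter: "hot" blows (misting a window) concentrate energy in 450-1300 Hz,
"cold" blows (cooling soup, and the type a spirometry maneuver resembles)
in 1500-4000 Hz.  The amplitude envelope follows the flow-rate curve of a
spirometry test: a fast rise to peak flow, then a decay whose shape encodes
airway condition — exponential for healthy airways, faster-than-exponential
for obstructive disease, and a Weibull-density profile with reduced total
volume for restrictive disease.

The generator produces labelled corpora with age- and gender-conditioned
parameters so the full feature-extraction and classification pipeline can be
exercised end to end.  The age dependence (older lungs decay faster and move
less total air) is a monotone stand-in for testing signal recovery, not a
physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal, write_wav

#: Pass-bands (Hz) of the two blow types.
PASS_BANDS = {"hot": (450.0, 1300.0), "cold": (1500.0, 4000.0)}

EnvelopeName = Literal["healthy", "obstructive", "restrictive"]


@dataclass(frozen=True)
class BlowParams:
    """Parameters of one synthetic blow.

    ``decay_rate`` is the exponential decay constant lambda (1/s) of the
    healthy envelope; the obstructive and restrictive shapes derive from it.
    ``capacity`` scales the restrictive envelope's time-integral relative to
    the healthy one (reduced vital capacity).
    """

    blow_type: Literal["cold", "hot"] = "cold"
    envelope: EnvelopeName = "healthy"
    duration: float = 6.0
    peak_amplitude: float = 0.9
    age: float = 40.0
    gender: int = 0
    noise_floor: float = 0.0
    seed: int = 0
    decay_rate: float = 1.0
    t_peak: float = 0.2
    obstructive_power: float = 1.6
    capacity: float = 0.6

    def __post_init__(self) -> None:
        if self.blow_type not in PASS_BANDS:
            raise ValueError(f"unknown blow_type {self.blow_type!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.peak_amplitude <= 1:
            raise ValueError("peak_amplitude must be in (0, 1]")


def make_age_effect(decay_slope: float = 0.01, energy_slope: float = 0.005):
    """Monotone age -> (decay-rate multiplier, total-energy multiplier) map.

    Older subjects exhale with faster flow decay and less total energy:
    multipliers 1 + decay_slope*(age-17) and 1 - energy_slope*(age-17).
    The default slopes encode a deliberately subtle signal; recovery
    studies that ask whether the pipeline can find a signal that is
    clearly present use a steeper decay slope (e.g. 0.05/year).
    """

    def age_effect(age: float) -> tuple[float, float]:
        return (1.0 + decay_slope * (age - 17.0),
                max(1.0 - energy_slope * (age - 17.0), 0.05))

    return age_effect


_default_age_effect = make_age_effect()


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a labelled synthetic corpus.

    Ages are drawn uniformly over ``age_range`` (the study population spans
    17-67 years); genders are balanced; the envelope class of each sample is
    drawn from ``class_proportions``.
    """

    n_samples: int = 100
    age_range: tuple[float, float] = (17.0, 67.0)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.6, "obstructive": 0.2, "restrictive": 0.2}
    )
    age_effect: Callable[[float], tuple[float, float]] = _default_age_effect
    blow_type: Literal["cold", "hot"] = "cold"
    duration: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.class_proportions:
            raise ValueError("class_proportions must be non-empty")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")


def flow_envelope(
    envelope: EnvelopeName,
    t: float | np.ndarray,
    duration: float,
    decay_rate: float = 1.0,
    t_peak: float = 0.2,
    obstructive_power: float = 1.6,
    capacity: float = 0.6,
) -> np.ndarray:
    """Flow-rate-shaped amplitude envelope, evaluated at time(s) ``t``.

    * ``healthy``: linear rise to 1.0 at ``t_peak`` then exp(-lambda (t - t_peak)).
    * ``obstructive``: same rise, then exp(-(lambda (t - t_peak))^p) with
      p > 1, i.e. decay faster than exponential.
    * ``restrictive``: Weibull-density shape whose time-integral equals
      ``capacity`` times the healthy integral at the same lambda.

    All shapes start at 0 flow.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0) or np.any(t_arr > duration):
        raise ValueError("t outside [0, duration]")
    if envelope in ("healthy", "obstructive"):
        rise = np.clip(t_arr / t_peak, 0.0, 1.0)
        tail = np.clip(t_arr - t_peak, 0.0, None)
        if envelope == "healthy":
            decay = np.exp(-decay_rate * tail)
        else:
            decay = np.exp(-((decay_rate * tail) ** obstructive_power))
        out = np.where(t_arr <= t_peak, rise, decay)
    elif envelope == "restrictive":
        # Weibull(k=2) density normalized to unit integral on [0, duration],
        # then scaled so the area matches `capacity` x the healthy area.
        healthy_area = t_peak / 2.0 + (1.0 - np.exp(-decay_rate * (duration - t_peak))) / decay_rate
        k_shape = 2.0
        scale = 1.5 / decay_rate
        pdf = (k_shape / scale) * (t_arr / scale) ** (k_shape - 1) * np.exp(-((t_arr / scale) ** k_shape))
        total = 1.0 - np.exp(-((duration / scale) ** k_shape))  # Weibull CDF at duration
        out = capacity * healthy_area * pdf / total
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    return out if out.ndim else np.float64(out)


def synth_blow(p: BlowParams, sample_rate: float = 44_100.0) -> AudioSignal:
    """Generate one blow: band-passed white noise under a flow envelope.

    The noise is filtered with a 4th-order Butterworth applied
    forward-backward (zero phase) at the blow-type pass-band, multiplied by
    the flow envelope, optionally mixed with broadband floor noise, and
    peak-normalized to ``p.peak_amplitude``.  Deterministic given the seed.
    """
    low, high = PASS_BANDS[p.blow_type]
    if sample_rate < 2 * high:
        raise ValueError(
            f"sample_rate {sample_rate} below Nyquist requirement {2 * high} "
            f"for the {p.blow_type} pass-band"
        )
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * sample_rate))
    noise = rng.standard_normal(n)
    sos = butter(4, [low, high], btype="bandpass", fs=sample_rate, output="sos")
    shaped = sosfiltfilt(sos, noise)
    t = np.arange(n) / sample_rate
    env = flow_envelope(
        p.envelope, t, p.duration,
        decay_rate=p.decay_rate, t_peak=p.t_peak,
        obstructive_power=p.obstructive_power, capacity=p.capacity,
    )
    out = shaped * env
    if p.noise_floor > 0:
        out = out + p.noise_floor * rng.standard_normal(n)
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (p.peak_amplitude / peak)
    return AudioSignal(samples=out, sample_rate=float(sample_rate))


def synth_corpus(
    spec: CorpusSpec, sample_rate: float = 44_100.0
) -> list[tuple[AudioSignal, float, int, str]]:
    """Generate a labelled corpus of (signal, age, gender, envelope) tuples.

    Older subjects get faster envelope decay and lower total energy through
    ``spec.age_effect``; genders alternate (balanced); per-sample noise seeds
    derive from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n_samples)
    names = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[k] for k in names])
    envelopes = rng.choice(names, size=spec.n_samples, p=probs)
    out = []
    for i in range(spec.n_samples):
        lam_mult, energy_mult = spec.age_effect(float(ages[i]))
        p = BlowParams(
            blow_type=spec.blow_type,
            envelope=str(envelopes[i]),
            duration=spec.duration,
            peak_amplitude=min(1.0, 0.9 * max(energy_mult, 0.05)),
            age=float(ages[i]),
            gender=i % 2,
            seed=int(rng.integers(0, 2**31 - 1)),
            decay_rate=1.0 * lam_mult,
        )
        out.append((synth_blow(p, sample_rate), p.age, p.gender, p.envelope))
    return out


def write_corpus(
    spec: CorpusSpec, out_dir: str | Path, sample_rate: float = 44_100.0
) -> Path:
    """Write a corpus as WAV files plus a ``labels.csv``; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = synth_corpus(spec, sample_rate)
    lines = ["file,age,gender,envelope,seed"]
    for i, (sig, age, gender, envelope) in enumerate(corpus):
        name = f"blow_{i:04d}.wav"
        write_wav(out_dir / name, sig)
        lines.append(f"{name},{age:.4f},{gender},{envelope},{spec.seed}")
    csv_path = out_dir / "labels.csv"
    csv_path.write_text("\n".join(lines) + "\n")
    return csv_path
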