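"""The 38 time-frequency features, checked against explicit-loop oracles."""

import numpy as np
import pytest

from blowspiro import AudioSignal, BandSet, CWDConfig, choi_williams, entropies
from blowspiro import extract_tf_features, joint_density, joint_moments, kurtosis
from blowspiro.errors import DegenerateInputError
from blowspiro.tf_features import (
    TF_FEATURE_NAMES,
    band_energy,
    band_freq_mean,
    band_freq_peak,
    band_spectral_info,
)

RATE = 44_100.0
EPS = 2.0**-30


def band_features_brute(pD, freqs, band, eps=EPS):
    """Loop-wise band energy share, frequency peak and mean frequency."""
    lo, hi = band
    n_t = pD.shape[1]
    shares, peaks, means = [], [], []
    for t in range(n_t):
        col = pD[:, t]
        col_sum = col.sum()
        in_band = [(f, col[i]) for i, f in enumerate(freqs) if lo <= f < hi]
        e = sum(v for _, v in in_band)
        shares.append(e / col_sum if col_sum > 0 else 0.0)
        if e > eps:
            best_f, best_v = in_band[0]
            for f, v in in_band:
                if v > best_v:
                    best_f, best_v = f, v
            peaks.append(best_f)
            means.append(sum(f * v for f, v in in_band) / e)
    mean_share = float(np.mean(shares))
    mean_peak = float(np.mean(peaks)) if peaks else 0.0
    mean_mean = float(np.mean(means)) if means else 0.0
    return mean_share, mean_peak, mean_mean


class TestBandFeatures:
    def test_band_partition_sums_to_one(self, cold_blow):
        tfd = choi_williams(cold_blow.samples[:1024], CWDConfig(), RATE)
        pD = joint_density(tfd)
        bands = BandSet.default(RATE / 2)
        total = sum(band_energy(pD, tfd.freqs, b)[1] for b in bands.edges)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_tone_energy_in_band_six(self):
        t = np.arange(1024) / RATE
        tfd = choi_williams(np.sin(2 * np.pi * 2000.0 * t), CWDConfig(), RATE)
        pD = joint_density(tfd)
        bands = BandSet.default(RATE / 2)
        energies = [band_energy(pD, tfd.freqs, b)[1] for b in bands.edges]
        assert np.argmax(energies) == 5  # 1500-3000 Hz

    def test_tone_band_frequency_features(self):
        t = np.arange(1024) / RATE
        tfd = choi_williams(np.sin(2 * np.pi * 2000.0 * t), CWDConfig(), RATE)
        pD = joint_density(tfd)
        bin_hz = tfd.freqs[1] - tfd.freqs[0]
        band = (1500.0, 3000.0)
        assert abs(band_freq_peak(pD, tfd.freqs, band) - 2000.0) <= bin_hz
        assert abs(band_freq_mean(pD, tfd.freqs, band) - 2000.0) <= 2 * bin_hz

    def test_peak_and_mean_stay_inside_band(self, cold_blow):
        tfd = choi_williams(cold_blow.samples[:1024], CWDConfig(), RATE)
        pD = joint_density(tfd)
        for band in BandSet.default(RATE / 2).edges:
            peak = band_freq_peak(pD, tfd.freqs, band)
            mean = band_freq_mean(pD, tfd.freqs, band)
            for v in (peak, mean):
                assert v == 0.0 or band[0] <= v < band[1]

    def test_uniform_band_mean_is_midpoint(self):
        freqs = np.arange(256) * 10.0  # 0..2550 Hz grid
        mfN = np.zeros(256)
        band_bins = (freqs >= 500) & (freqs < 1000)
        mfN[band_bins] = 1.0 / band_bins.sum()
        pD = np.outer(mfN, np.full(32, 1 / 32))
        got = band_freq_mean(pD, freqs, (500.0, 1000.0))
        # discrete mean of the uniform grid 500,510,...,990
        assert got == pytest.approx(745.0, abs=5.0)

    def test_brute_force_band_oracle_on_small_frames(self):
        rng = np.random.default_rng(3)
        frame = rng.standard_normal(64)
        tfd = choi_williams(frame, CWDConfig(frame_len=64), RATE)
        pD = joint_density(tfd)
        for band in [(0.0, 5000.0), (5000.0, 12_000.0), (12_000.0, RATE / 2)]:
            share, peak, mean = band_features_brute(pD, tfd.freqs, band)
            _, got_share = band_energy(pD, tfd.freqs, band)
            assert got_share == pytest.approx(share, rel=1e-8)
            assert band_freq_peak(pD, tfd.freqs, band) == pytest.approx(peak, rel=1e-8)
            assert band_freq_mean(pD, tfd.freqs, band) == pytest.approx(mean, rel=1e-8)

    def test_spectral_info_uniform_and_delta(self):
        freqs = np.arange(256, dtype=float)
        uniform = np.full(256, 1 / 256)
        assert band_spectral_info(uniform, freqs, (0.0, 256.0)) == pytest.approx(8.0)
        delta = np.zeros(256)
        delta[10] = 1.0
        # bins at the eps floor contribute -log2(eps) = 30 bits each
        lo_band = band_spectral_info(delta, freqs, (0.0, 20.0))
        hi_band = band_spectral_info(delta, freqs, (20.0, 256.0))
        assert hi_band == pytest.approx(30.0)
        assert lo_band < hi_band


class TestEntropiesAndKurtosis:
    def test_uniform_entropies(self):
        h_t, h_f, h_tf = entropies(np.full(1024, 1 / 1024), np.full(512, 1 / 512))
        assert (h_t, h_f, h_tf) == pytest.approx((10.0, 9.0, 19.0))

    def test_degenerate_point_mass(self):
        mt = np.zeros(64); mt[3] = 1.0
        mf = np.zeros(32); mf[7] = 1.0
        assert entropies(mt, mf) == pytest.approx((0.0, 0.0, 0.0))

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            entropies(np.full(10, 0.2), np.full(10, 0.1))

    def test_kurtosis_uniform(self):
        # continuous uniform kurtosis is 9/5; discrete at n = 1024 is within 0.01
        assert kurtosis(np.full(1024, 1 / 1024)) == pytest.approx(1.8, abs=0.01)

    def test_kurtosis_gaussian(self):
        x = np.linspace(0, 1, 1024)
        dens = np.exp(-0.5 * ((x - 0.5) / 0.05) ** 2)
        dens /= dens.sum()
        assert kurtosis(dens) == pytest.approx(3.0, abs=0.05)

    def test_kurtosis_two_point_masses(self):
        dens = np.zeros(100)
        dens[20] = dens[80] = 0.5
        assert kurtosis(dens) == pytest.approx(1.0)

    def test_kurtosis_zero_variance(self):
        dens = np.zeros(100); dens[50] = 1.0
        with pytest.raises(DegenerateInputError):
            kurtosis(dens)


class TestJointMoments:
    def test_separable_distribution_momc_equals_momm(self):
        rng = np.random.default_rng(1)
        mt = rng.random(128); mt /= mt.sum()
        mf = rng.random(64); mf /= mf.sum()
        cwdn = np.outer(mf, mt)
        momc11, momc77, momc15, momm11, momm77, momm15 = joint_moments(cwdn, mt, mf)
        assert momc11 == pytest.approx(momm11, abs=1e-12)
        assert momc77 == pytest.approx(momm77, abs=1e-12)
        assert momc15 == pytest.approx(momm15, abs=1e-12)

    def test_uniform_moments_converge_to_reciprocal_orders(self):
        # each axis factor of t^n under a uniform density tends to 1/(n+1)
        for n, expected in [(256, None), (4096, None)]:
            mt = np.full(n, 1 / n); mf = np.full(n // 2, 2 / n)
            moms = joint_moments(np.outer(mf, mt), mt, mf)
            if n == 4096:
                assert moms[3] == pytest.approx(1 / 4, abs=1e-6)
                assert moms[4] == pytest.approx(1 / 64, rel=0.01)
                assert moms[5] == pytest.approx(1 / 256, rel=0.01)

    def test_corner_point_mass_gives_unit_moments(self):
        mt = np.zeros(32); mt[-1] = 1.0
        mf = np.zeros(16); mf[-1] = 1.0
        moms = joint_moments(np.outer(mf, mt), mt, mf)
        assert np.allclose(moms, 1.0)


class TestExtraction:
    def test_exactly_38_features_28_of_them_band(self, cold_blow, fast_cfg):
        tf = extract_tf_features(cold_blow, fast_cfg)
        assert tf.as_array().size == 38
        assert len(TF_FEATURE_NAMES) == 38
        band_names = [n for n in TF_FEATURE_NAMES
                      if n[:-1] in ("e_bn", "f_cres", "f_med", "ie_bn")]
        assert len(band_names) == 28

    def test_h_tf_identity_exact(self, cold_blow, fast_cfg):
        tf = extract_tf_features(cold_blow, fast_cfg)
        assert tf.h_tf == tf.h_t + tf.h_f

    def test_amplitude_scale_invariance(self, cold_blow, fast_cfg):
        a = extract_tf_features(cold_blow, fast_cfg).as_array()
        scaled = AudioSignal(samples=0.1 * cold_blow.samples, sample_rate=RATE)
        b = extract_tf_features(scaled, fast_cfg).as_array()
        assert np.allclose(a, b, atol=1e-9)

    def test_cold_vs_hot_band_ordering(self, cold_blow, hot_blow, fast_cfg):
        cold = extract_tf_features(cold_blow, fast_cfg)
        hot = extract_tf_features(hot_blow, fast_cfg)
        assert cold.e_bn[5] > cold.e_bn[2]  # cold: 1500-3000 Hz dominates 250-550
        assert hot.e_bn[2] > hot.e_bn[5]    # hot: energy near 450-1300 Hz instead

    def test_too_short_signal_rejected(self, fast_cfg):
        sig = AudioSignal(samples=np.ones(100), sample_rate=RATE)
        with pytest.raises(ValueError):
            extract_tf_features(sig, fast_cfg)


def test_band_set_validation():
    with pytest.raises(ValueError):
        BandSet(edges=((0.0, 100.0), (200.0, 300.0)))  # gap
    default = BandSet.default(22_050.0)
    assert default.edges[0] == (0.0, 80.0)
    assert default.edges[-1] == (3000.0, 22_050.0)
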