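"""Extract the 42-feature vector from one synthetic exhalation.

Three spirometer-like features come from the STFT decibel spectrogram
(proxies for FVC, FEV1, PEF); 38 time-frequency features come from the
Choi-Williams distribution and its marginal densities; gender completes
the vector.
"""

from blowspiro import BlowParams, extract_spiro_features, extract_tf_features, synth_blow
from blowspiro.tf_features import TF_FEATURE_NAMES

sig = synth_blow(BlowParams(blow_type="cold", envelope="healthy", duration=6.0, seed=7))

spiro = extract_spiro_features(sig)
print("spirometer-like features (dB sums over the reference-max spectrogram):")
print(f"  total_dec         = {spiro.total_dec:12.1f}   (~ FVC: total exhaled 'volume')")
print(f"  total_dec_1st_sec = {spiro.total_dec_1st_sec:12.1f}   (~ FEV1: first-second share)")
print(f"  max_peak          = {spiro.max_peak:12.1f}   (~ PEF: spectrogram dynamic range, dB)")

tf = extract_tf_features(sig)
print("\ntime-frequency features (Choi-Williams, 7 bands + full range):")
print("  band energy shares:", " ".join(f"{e:.3f}" for e in tf.e_bn),
      "(sum to 1; band 6 = 1500-3000 Hz dominates a cold blow)")
print(f"  entropies: H_t = {tf.h_t:.2f} bits, H_f = {tf.h_f:.2f} bits, "
      f"H_tf = {tf.h_tf:.2f} bits (identity H_tf = H_t + H_f)")
print(f"  kurtosis of the time marginal: {tf.k:.2f}")
print(f"  all {len(TF_FEATURE_NAMES)} features:", )
for name, val in zip(TF_FEATURE_NAMES, tf.as_array()):
    print(f"    {name:10s} {val:12.5g}")
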