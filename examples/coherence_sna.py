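"""Wavelet coherence between a scalp component and depth contacts.

Calibrates per-frequency significance thresholds on white-noise
surrogates, computes the coherence of the selected scalp component with
every SEEG bipolar pair, quantifies each plane by its significant
normalized area (SNA), and applies the robust outlier rule to find the
pairs that stand out.
"""

from ictalcoh import WaveletParams, calibrate_threshold, detect_outlier_pairs
from ictalcoh.pipeline import analyze_depth_session

params = WaveletParams()
thresholds = calibrate_threshold(params, fs=256.0, duration=30.0,
                                 alpha=0.05, n=200, seed=0)
print(f"thresholds over {len(thresholds.freqs)} frequencies: "
      f"{thresholds.threshold.min():.3f}-{thresholds.threshold.max():.3f}")

result = analyze_depth_session(eccentricity=0.8, seed=3,
                               thresholds=thresholds)
print(f"selected component: IC{result.selected_component}")
print(f"SNA against the true SOZ pair: {result.sna_soz:.3f}")
print(f"most coherent pair: {result.max_pair} "
      f"(SNA {result.max_pair_sna:.3f}, "
      f"{result.max_pair_distance_mm:.1f} mm from the dipole)")
print(f"dipole-to-SOZ-centre error: {result.d_soz_mm:.1f} mm")
# SNA is the fraction of non-edge time-frequency points whose coherence
# exceeds the per-frequency surrogate threshold; under independence it
# stays near the 5% significance level.
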