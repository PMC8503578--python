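import numpy as np
import pytest

from ictalcoh.coherence import (CoherencePairSummary, WaveletParams,
                                calibrate_threshold, detect_outlier_pairs,
                                morlet_tf, naive_wavelet_coherence,
                                summarize_pair, wavelet_coherence,
                                zscore_tf_display)

FS = 256.0


@pytest.fixture(scope="module")
def params():
    return WaveletParams()


class TestMorletTransform:
    def test_wavelet_width_formula(self, params):
        # 2 sigma = xi / (pi f): at f = 7/pi Hz the width is exactly 1 s
        assert 2 * params.sigma(7.0 / np.pi) == pytest.approx(1.0)

    def test_frequency_grid_count_and_spacing(self, params):
        f = params.frequencies()
        assert len(f) == int(np.floor(10 * np.log2(100 / 5))) + 1 == 44
        np.testing.assert_allclose(np.diff(np.log2(f)), 0.1, rtol=1e-12)
        assert f[0] == 5.0 and f[-1] <= 100.0

    def test_pure_sine_peaks_at_nearest_grid_frequency(self, params):
        t = np.arange(int(20 * FS)) / FS
        tf = morlet_tf(np.sin(2 * np.pi * 20.0 * t), FS, params)
        row = np.argmax(np.abs(tf.coefficients).mean(axis=1))
        f = params.frequencies()
        assert tf.freqs[row] == f[np.argmin(np.abs(f - 20.0))]

    def test_unit_sine_amplitude_is_one_off_edges(self, params):
        t = np.arange(int(20 * FS)) / FS
        tf = morlet_tf(np.sin(2 * np.pi * 20.0 * t), FS, params)
        row = np.argmin(np.abs(tf.freqs - 20.0))
        mid = np.abs(tf.coefficients[row, int(5 * FS):int(15 * FS)])
        assert mid.mean() == pytest.approx(1.0, abs=1e-3)

    def test_record_shorter_than_wavelet_rejected(self, params):
        with pytest.raises(ValueError, match="shorter"):
            morlet_tf(np.zeros(100), FS, params)


class TestZscoreDisplay:
    def test_baseline_points_standardised_per_row(self, params):
        rng = np.random.default_rng(0)
        tf = morlet_tf(rng.normal(size=int(10 * FS)), FS, params)
        z = zscore_tf_display(tf)
        a = np.abs(tf.coefficients)
        for i in (0, 20, 43):
            base = a[i] <= np.quantile(a[i], 0.2)
            assert z[i][base].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[i][base].std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_amplitude_row_maps_to_zero(self, params):
        t = np.arange(int(10 * FS)) / FS
        tf = morlet_tf(np.sin(2 * np.pi * 20 * t), FS, params)
        row = np.argmin(np.abs(tf.freqs - 20.0))
        keep = slice(int(3 * FS), int(7 * FS))
        tf.coefficients = tf.coefficients[:, keep] * 0 + \
            tf.coefficients[:, keep]
        tf.coefficients[row] = 1.0 + 0j
        z = zscore_tf_display(tf)
        assert np.abs(z[row]).max() < 1e-6

    def test_injected_burst_stands_out(self, params):
        rng = np.random.default_rng(1)
        x = 0.5 * rng.normal(size=int(12 * FS))
        t = np.arange(x.size) / FS
        burst = (t > 6) & (t < 7)
        x[burst] += 5 * np.sin(2 * np.pi * 40 * t[burst])
        tf = morlet_tf(x, FS, params)
        z = zscore_tf_display(tf)
        row = np.argmin(np.abs(tf.freqs - 40.0))
        burst_z = z[row, int(6.2 * FS):int(6.8 * FS)].min()
        background_z = np.median(z[row, int(1 * FS):int(5 * FS)])
        assert burst_z > 5
        assert burst_z > 3 * background_z


class TestCoherence:
    def test_self_coherence_is_unity(self, params):
        rng = np.random.default_rng(0)
        tf = morlet_tf(rng.normal(size=int(6 * FS)), FS, params)
        cm = wavelet_coherence(tf, tf)
        assert np.abs(cm.coherence[~cm.edge_mask] - 1.0).max() < 1e-9

    def test_bounds_and_symmetry(self, params):
        rng = np.random.default_rng(1)
        tx = morlet_tf(rng.normal(size=int(6 * FS)), FS, params)
        ty = morlet_tf(rng.normal(size=int(6 * FS)), FS, params)
        cxy = wavelet_coherence(tx, ty)
        cyx = wavelet_coherence(ty, tx)
        assert cxy.coherence.min() >= 0.0
        assert cxy.coherence.max() <= 1.0
        np.testing.assert_allclose(cxy.coherence, cyx.coherence, atol=1e-12)

    def test_edge_mask_wider_at_lower_frequencies(self, params):
        rng = np.random.default_rng(2)
        tf = morlet_tf(rng.normal(size=int(8 * FS)), FS, params)
        cm = wavelet_coherence(tf, tf)
        widths = cm.edge_mask.sum(axis=1)
        assert widths[0] > widths[-1]

    def test_small_delay_preserves_high_coherence(self, params):
        rng = np.random.default_rng(3)
        fs = 512.0
        x = rng.normal(size=int(8 * fs))
        d = 1  # one sample = 1.95 ms
        tx = morlet_tf(x[d:], fs, params)
        ty = morlet_tf(x[:-d], fs, params)
        cm = wavelet_coherence(tx, ty)
        # high coherence needs the delay small against both the wavelet
        # width and the phase-dispersion scale of the 10-voice frequency
        # smoother (phase 2*pi*f*d must barely rotate across the band)
        rows = cm.freqs <= 30.0
        keep = rows[:, None] & ~cm.edge_mask
        assert cm.coherence[keep].min() > 0.99

    def test_grid_mismatch_rejected(self, params):
        rng = np.random.default_rng(4)
        tx = morlet_tf(rng.normal(size=int(6 * FS)), FS, params)
        ty = morlet_tf(rng.normal(size=int(6 * FS)), FS,
                       WaveletParams(fmin=6.0))
        with pytest.raises(ValueError, match="grid"):
            wavelet_coherence(tx, ty)

    def test_matches_naive_direct_implementation(self, params):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, int(2 * FS)))
        cm = wavelet_coherence(morlet_tf(x, FS, params),
                               morlet_tf(y, FS, params))
        c_naive, edge_naive = naive_wavelet_coherence(x, y, FS, params)
        assert np.abs(cm.coherence - c_naive).max() < 1e-6
        np.testing.assert_array_equal(cm.edge_mask, edge_naive)


class TestSurrogateThresholds:
    def test_alpha_one_thresholds_vanish(self, params):
        thr = calibrate_threshold(params, FS, 5.0, alpha=1.0, n=60, seed=0)
        assert not thr.threshold.any()

    def test_deterministic_under_seed(self, params):
        t1 = calibrate_threshold(params, FS, 5.0, n=60, seed=5)
        t2 = calibrate_threshold(params, FS, 5.0, n=60, seed=5)
        np.testing.assert_array_equal(t1.threshold, t2.threshold)

    def test_doubled_smoothing_lowers_thresholds(self, params):
        wide = WaveletParams(time_smoothing_sigmas=40.0)
        t1 = calibrate_threshold(params, FS, 12.0, n=60, seed=0)
        t2 = calibrate_threshold(wide, FS, 12.0, n=60, seed=0)
        assert (t2.threshold < t1.threshold).all()

    def test_pink_noise_thresholds_close_to_white(self, params):
        """1/f surrogates shift thresholds by < 20% relative (reported)."""
        tw = calibrate_threshold(params, FS, 10.0, n=60, seed=0)
        tp = calibrate_threshold(params, FS, 10.0, n=60, seed=0,
                                 noise="pink")
        rel = np.abs(tp.threshold - tw.threshold) / tw.threshold
        assert np.median(rel) < 0.2

    def test_few_realizations_warn(self, params):
        with pytest.warns(UserWarning, match="realizations"):
            calibrate_threshold(params, FS, 5.0, n=10, seed=0)


class TestSummaries:
    def test_counting_arithmetic(self, params):
        from ictalcoh.coherence import CoherenceMap, SurrogateThreshold

        freqs = np.array([10.0])
        coh = np.linspace(0, 1, 102)[None, :]
        edge = np.zeros_like(coh, bool)
        edge[0, :2] = True  # 100 non-edge points
        cm = CoherenceMap(freqs, np.arange(102) / FS, coh, edge)
        thr = SurrogateThreshold(freqs, np.array([coh[0, -7] + 1e-12]),
                                 0.05, 200, 0)
        s = summarize_pair(cm, thr)
        assert s.total == 100
        assert s.ns == 6
        assert s.sna == pytest.approx(0.06)

    def test_identical_signals_saturate_sna(self, params):
        rng = np.random.default_rng(6)
        tf = morlet_tf(rng.normal(size=int(6 * FS)), FS, params)
        thr = calibrate_threshold(params, FS, 6.0, n=60, seed=1)
        s = summarize_pair(wavelet_coherence(tf, tf), thr)
        assert s.sna > 0.999

    def test_independent_noise_sna_near_alpha(self, params):
        thr = calibrate_threshold(params, FS, 10.0, n=100, seed=2)
        rng = np.random.default_rng(7)
        snas = []
        for _ in range(8):
            tx = morlet_tf(rng.normal(size=int(10 * FS)), FS, params)
            ty = morlet_tf(rng.normal(size=int(10 * FS)), FS, params)
            snas.append(summarize_pair(wavelet_coherence(tx, ty), thr).sna)
        assert np.mean(snas) == pytest.approx(0.05, abs=0.02)


class TestOutlierRule:
    def _summaries(self, ns_values):
        return [CoherencePairSummary(0, f"p{i}", n, 1000)
                for i, n in enumerate(ns_values)]

    def test_hand_computed_example(self):
        # Ns {0,1,2,2,3,50}: m=2, Q1=1.25, Q3=2.75, thr = 2+5*1.5 = 9.5
        rule, selected = detect_outlier_pairs(
            self._summaries([0, 1, 2, 2, 3, 50]))
        assert rule.m == 2.0
        assert rule.q25 == pytest.approx(1.25)
        assert rule.q75 == pytest.approx(2.75)
        assert rule.threshold == pytest.approx(9.5)
        assert [s.ns for s in selected] == [50]

    def test_all_equal_selects_nothing(self):
        rule, selected = detect_outlier_pairs(self._summaries([7, 7, 7, 7]))
        assert rule.threshold == 7.0
        assert selected == []

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            detect_outlier_pairs(self._summaries([1, 2, 3]))


class TestPhaseScrambleSurrogates:
    def test_preserves_amplitude_spectrum(self, params):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1024)
        from ictalcoh.coherence import _phase_scramble

        y = _phase_scramble(rng, x)
        np.testing.assert_allclose(np.abs(np.fft.rfft(y)),
                                   np.abs(np.fft.rfft(x)), rtol=1e-9)
        assert not np.allclose(y, x)

    def test_thresholds_from_scrambled_reference(self, params):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, int(8 * FS)))
        thr = calibrate_threshold(params, FS, 8.0, n=60, seed=0,
                                  noise="phase_scramble", reference=(x, y))
        assert (thr.threshold > 0).all() and (thr.threshold < 1).all()

    def test_reference_required(self, params):
        with pytest.raises(ValueError, match="reference"):
            calibrate_threshold(params, FS, 8.0, n=60, seed=0,
                                noise="phase_scramble")
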