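import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalcoh.ica import (ComponentScreen, ICADecomposition, rank_candidates,
                          run_infomax, screen_components,
                          screen_outlier_topography)
from ictalcoh.io import CH_SCALP, Recording


def _mixture(seed, n_ch=20, n_src=3, n_samp=10000, noise=0.02):
    rng = np.random.default_rng(seed)
    s = rng.laplace(size=(n_src, n_samp))  # super-Gaussian sources
    a = rng.normal(size=(n_ch, n_src))
    x = a @ s + noise * rng.normal(size=(n_ch, n_samp))
    rec = Recording(x, [f"E{i}" for i in range(n_ch)], 256.0,
                    [CH_SCALP] * n_ch)
    return rec, s, a


def _matched_correlations(sources, activations):
    c = np.corrcoef(np.vstack([sources, activations]))
    k = sources.shape[0]
    return np.abs(c[:k, k:]).max(axis=1)


def test_recovers_super_gaussian_sources():
    rec, s, _ = _mixture(0)
    dec = run_infomax(rec, n_components=3, seed=0)
    assert _matched_correlations(s, dec.activations).min() > 0.95


def test_identity_mixture_gives_permutation_scaling():
    """Already-independent inputs: mixing ~ permutation x diagonal."""
    rng = np.random.default_rng(1)
    s = rng.laplace(size=(4, 8000))
    rec = Recording(s, list("abcd"), 256.0, [CH_SCALP] * 4)
    dec = run_infomax(rec, n_components=4, seed=0)
    m = np.abs(dec.mixing)
    m = m / m.max(axis=0)
    # in each column exactly one dominant entry, all others small
    for c in range(4):
        col = np.sort(m[:, c])
        assert col[-1] == 1.0
        assert col[-2] < 0.05


def test_reconstruction_identity_and_unit_variance():
    rec, _, _ = _mixture(2)
    dec = run_infomax(rec, n_components=3, seed=0)
    np.testing.assert_allclose(dec.unmixing @ dec.mixing, np.eye(3),
                               atol=1e-6)
    np.testing.assert_allclose(dec.activations.std(axis=1), 1.0, rtol=1e-9)
    recon = dec.reconstruct()
    rel = np.linalg.norm(recon - rec.data) / np.linalg.norm(rec.data)
    assert rel < 1e-2  # sensor noise lives outside the 3-D source subspace


def test_rank_deficient_data_reduced_with_warning():
    rng = np.random.default_rng(3)
    base = rng.laplace(size=(2, 5000))
    a = rng.normal(size=(6, 2))
    rec = Recording(a @ base, [f"E{i}" for i in range(6)], 256.0,
                    [CH_SCALP] * 6)
    with pytest.warns(UserWarning, match="rank-deficient"):
        dec = run_infomax(rec, n_components=5, seed=0)
    assert dec.n_components == 2


def test_deterministic_under_seed():
    rec, _, _ = _mixture(4)
    d1 = run_infomax(rec, n_components=3, seed=11)
    d2 = run_infomax(rec, n_components=3, seed=11)
    np.testing.assert_array_equal(d1.unmixing, d2.unmixing)


class TestScreening:
    def test_one_hot_topography_flagged_infinite_z(self):
        v = np.zeros(20)
        v[7] = 1.0
        flag, z = screen_outlier_topography(v)
        assert flag and np.isinf(z)

    def test_all_equal_topography_not_flagged(self):
        flag, z = screen_outlier_topography(np.full(15, 3.3))
        assert not flag and z == 0.0

    def test_gaussian_topographies_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flags = sum(screen_outlier_topography(rng.normal(size=30))[0]
                    for _ in range(2000))
        assert flags == 0

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(-50, 50).filter(lambda s: abs(s) > 1e-3),
           seed=st.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        v = np.random.default_rng(seed).normal(size=12)
        f1, z1 = screen_outlier_topography(v)
        f2, z2 = screen_outlier_topography(scale * v)
        assert f1 == f2
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError, match="3 electrodes"):
            screen_outlier_topography([1.0, 2.0])


class TestRanking:
    def _screen(self, cid, gof, flagged=False, var=1.0):
        return ComponentScreen(cid, flagged, 5.0, gof=gof, variance=var)

    def test_gof_threshold_and_descending_order(self):
        screens = [self._screen(0, 95.0), self._screen(1, 80.0),
                   self._screen(2, 92.0)]
        assert rank_candidates(screens) == [0, 2]

    def test_all_flagged_gives_empty_with_warning(self):
        screens = [self._screen(0, 95.0, flagged=True)]
        with pytest.warns(UserWarning, match="no components"):
            assert rank_candidates(screens) == []

    def test_gof_ties_broken_by_variance(self):
        screens = [self._screen(0, 95.0, var=1.0),
                   self._screen(1, 95.0, var=5.0)]
        assert rank_candidates(screens) == [1, 0]


def test_ictal_component_survives_screening_and_ranking(small_session, head):
    """On a shallow synthetic session the component matching the true
    generator is retained (unflagged, GOF > 90) and GOF-ranked."""
    from ictalcoh.dipole import fill_gof
    from ictalcoh.io import CH_SCALP
    from ictalcoh.preprocess import (EpochSpec, FilterSpec, bandpass_fir,
                                     extract_epoch)

    scalp = small_session["scalp"]
    gt = small_session["gt"]
    onset = small_session["sources"][0].onset_time
    epoch = extract_epoch(bandpass_fir(scalp, FilterSpec()),
                          EpochSpec(onset)).pick(CH_SCALP)
    dec = run_infomax(epoch, n_components=8, seed=0, max_iter=80)
    truth = gt.scalp_mixing - gt.scalp_mixing.mean()
    best = max(range(8), key=lambda c: abs(np.corrcoef(dec.mixing[:, c],
                                                       truth)[0, 1]))
    assert abs(np.corrcoef(dec.mixing[:, best], truth)[0, 1]) > 0.95
    screens = screen_components(dec)
    elec = small_session["sensors"].scalp_positions()
    fill_gof(dec, screens, elec, head, n_restarts=5, seed=0)
    assert best in rank_candidates(screens)
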