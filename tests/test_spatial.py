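import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalcoh.spatial import (SOZDefinition, coherence_distance_correlation,
                              distance_profile, lowess_smooth, pair_midpoint,
                              soz_error, spatial_summary)

coords3 = st.tuples(*[st.floats(-100, 100) for _ in range(3)])


class TestMidpoint:
    def test_simple_midpoint(self):
        np.testing.assert_array_equal(pair_midpoint([0, 0, 0], [2, 0, 0]),
                                      [1, 0, 0])

    def test_identical_points(self):
        np.testing.assert_array_equal(pair_midpoint([3, 4, 5], [3, 4, 5]),
                                      [3, 4, 5])

    @settings(max_examples=30, deadline=None)
    @given(a=coords3, b=coords3)
    def test_permutation_symmetry(self, a, b):
        np.testing.assert_array_equal(pair_midpoint(a, b),
                                      pair_midpoint(b, a))


class TestDistanceProfile:
    def test_three_four_five(self):
        labels, d = distance_profile([0, 0, 0], {"p": [3.0, 4.0, 0.0]})
        assert labels == ["p"] and d[0] == pytest.approx(5.0)

    def test_dipole_on_midpoint_gives_zero(self):
        _, d = distance_profile([1, 2, 3], {"p": [1.0, 2.0, 3.0]})
        assert d[0] == 0.0

    def test_missing_coordinates_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            labels, d = distance_profile(
                [0, 0, 0], {"a": [1.0, 0.0, 0.0],
                            "b": [np.nan, 0.0, 0.0]})
        assert labels == ["a"]

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(0)
        mids = {f"p{i}": rng.normal(size=3) * 30 for i in range(6)}
        dip = rng.normal(size=3) * 20
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(size=3) * 50
        mids_r = {k: q @ v + t for k, v in mids.items()}
        _, d0 = distance_profile(dip, mids)
        _, d1 = distance_profile(q @ dip + t, mids_r)
        np.testing.assert_allclose(d0, d1, rtol=1e-10)


class TestSozError:
    def test_center_is_coordinate_mean_and_error_zero(self):
        coords = {"a": np.array([0.0, 0, 0]), "b": np.array([2.0, 0, 0]),
                  "c": np.array([4.0, 0, 0])}
        soz = SOZDefinition.from_contacts(["a", "b", "c"], coords)
        np.testing.assert_array_equal(soz.center, [2, 0, 0])
        assert soz_error([2, 0, 0], soz) == 0.0

    def test_off_center_error(self):
        coords = {"a": np.array([0.0, 0, 0]), "b": np.array([2.0, 0, 0]),
                  "c": np.array([4.0, 0, 0])}
        soz = SOZDefinition.from_contacts(["a", "b", "c"], coords)
        assert soz_error([2, 3, 0], soz) == pytest.approx(3.0)

    def test_empty_soz_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            SOZDefinition.from_contacts([], {})


class TestCorrelation:
    def test_exactly_decreasing_line(self):
        r, pr, rho, prho = coherence_distance_correlation(
            [0.0, 0.5, 1.0], [1.0, 0.5, 0.0])
        assert r == pytest.approx(-1.0)
        assert rho == pytest.approx(-1.0)

    def test_shuffled_pairs_uncorrelated(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.permutation(rng.normal(size=30))
            r, *_ = coherence_distance_correlation(x, y)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1
        assert np.mean(np.abs(rs)) < 0.35

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = coherence_distance_correlation([1.0, 1.0, 1.0],
                                                 [0.0, 1.0, 2.0])
        assert all(np.isnan(v) for v in out)


class TestLowess:
    def test_constant_input_constant_fit(self):
        x = np.arange(10.0)
        fit = lowess_smooth(x, np.full(10, 2.5))
        np.testing.assert_allclose(fit, 2.5, atol=1e-12)

    def test_exact_line_reproduced(self):
        x = np.linspace(0, 1, 20)
        y = 3.0 * x - 1.0
        np.testing.assert_allclose(lowess_smooth(x, y), y, atol=1e-9)

    def test_noisy_monotone_data_smooths_monotone(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 60)
        y = 2 * x + 0.05 * rng.normal(size=60)
        fit = lowess_smooth(x, y, span=0.7)
        assert np.all(np.diff(fit) > 0)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            lowess_smooth(np.arange(10.0), np.arange(10.0), span=1.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            lowess_smooth([1, 2, 3], [1, 2, 3])


def test_spatial_summary_assembles_profile():
    mids = {"a": np.array([10.0, 0, 0]), "b": np.array([20.0, 0, 0]),
            "c": np.array([30.0, 0, 0]), "d": np.array([40.0, 0, 0])}
    sna = {"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.05}
    coords = {"k1": np.array([8.0, 0, 0]), "k2": np.array([12.0, 0, 0])}
    soz = SOZDefinition.from_contacts(["k1", "k2"], coords)
    s = spatial_summary([0.0, 0, 0], mids, sna, soz)
    assert s.max_coh_pair == "a"
    assert s.max_coh_distance_mm == pytest.approx(10.0)
    assert s.d_soz_mm == pytest.approx(10.0)
    assert s.pearson_r < 0 and s.spearman_rho == pytest.approx(-1.0)
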