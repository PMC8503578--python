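"""Forward-model checks against closed forms and physical symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalcoh.sphere import HeadModel, scalp_potentials, seeg_potentials


def axial_closed_form(p_nam, t, head):
    """On-axis surface potential of a radial dipole at eccentricity t.

    Geometric-series sum of the boundary-corrected multipole expansion:
    V = p (2/(1-t)^2 + 1/(1-t)) / (4 pi sigma R^2).
    """
    rm = head.radius * 1e-3
    pref = p_nam * 1e-9 / (4 * np.pi * head.conductivity * rm**2)
    return pref * (2 / (1 - t) ** 2 + 1 / (1 - t))


def antipodal_closed_form(p_nam, t, head):
    # P_n(-1) = (-1)^n flips the sign of the whole series at the antipode
    rm = head.radius * 1e-3
    pref = p_nam * 1e-9 / (4 * np.pi * head.conductivity * rm**2)
    return -pref * (2 / (1 + t) ** 2 + 1 / (1 + t))


@pytest.mark.parametrize("ecc", [0.0, 0.2, 0.4, 0.6, 0.8, 0.9])
def test_radial_dipole_matches_axial_closed_form(head, ecc):
    R = head.radius
    elec = np.array([[0.0, 0.0, R], [0.0, 0.0, -R]])
    v = scalp_potentials([0, 0, ecc * R], [0, 0, 10.0], elec, head,
                         average_reference=False)
    assert v[0] == pytest.approx(axial_closed_form(10.0, ecc, head), rel=1e-9)
    assert v[1] == pytest.approx(antipodal_closed_form(10.0, ecc, head),
                                 rel=1e-8, abs=1e-12)


def test_center_dipole_symmetry_and_equator_null(head):
    """Radial dipole at the centre: potential ~ cos(theta), zero on equator."""
    R = head.radius
    th = np.linspace(0, np.pi, 13)
    elec = np.column_stack([R * np.sin(th), np.zeros_like(th),
                            R * np.cos(th)])
    v = scalp_potentials([0, 0, 0], [0, 0, 10.0], elec, head,
                         average_reference=False)
    expected = axial_closed_form(10.0, 0.0, head) * np.cos(th)
    np.testing.assert_allclose(v, expected, atol=1e-15)
    # azimuthal symmetry about the moment axis
    phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ring = np.column_stack([R * np.sin(1.0) * np.cos(phi),
                            R * np.sin(1.0) * np.sin(phi),
                            np.full_like(phi, R * np.cos(1.0))])
    vr = scalp_potentials([0, 0, 0], [0, 0, 10.0], ring, head,
                          average_reference=False)
    np.testing.assert_allclose(vr, vr[0], rtol=1e-12)


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 100))
def test_forward_linearity_and_superposition(scale, seed):
    head = HeadModel()
    rng = np.random.default_rng(seed)
    elec = rng.normal(size=(15, 3))
    elec = elec / np.linalg.norm(elec, axis=1, keepdims=True) * head.radius
    pos = rng.normal(size=3)
    pos = pos / np.linalg.norm(pos) * 0.6 * head.radius
    p1, p2 = rng.normal(size=(2, 3)) * 10
    v1 = scalp_potentials(pos, p1, elec, head)
    v2 = scalp_potentials(pos, p2, elec, head)
    v12 = scalp_potentials(pos, p1 + scale * p2, elec, head)
    np.testing.assert_allclose(v12, v1 + scale * v2, rtol=1e-10,
                               atol=1e-16)


def test_scalp_visibility_decreases_with_depth(head):
    """Monotone surface-RMS growth with eccentricity at fixed moment.

    Measured on a dense uniform sampling of the sphere: a sparse cap can
    miss the increasingly focal peak of a very shallow source, but the
    field itself is monotone in eccentricity.
    """
    k = np.arange(400)
    ga = np.pi * (3 - np.sqrt(5))
    z = 1 - 2 * (k + 0.5) / 400
    r = np.sqrt(1 - z**2)
    dense = head.radius * np.column_stack([r * np.cos(ga * k),
                                           r * np.sin(ga * k), z])
    u = np.array([0.5, -0.3, 0.81])
    u /= np.linalg.norm(u)
    rms = []
    for ecc in [0.1, 0.3, 0.5, 0.7, 0.8, 0.9]:
        v = scalp_potentials(head.center + ecc * head.radius * u, 20.0 * u,
                             dense, head)
        rms.append(np.sqrt(np.mean(v**2)))
    assert np.all(np.diff(rms) > 0)


def test_shallow_vs_deep_rms_ratio_exceeds_one(head, cap_positions):
    u = np.array([0.0, 0.0, 1.0])
    v_deep = scalp_potentials([0, 0, 0.4 * head.radius], 10 * u,
                              cap_positions, head)
    v_shallow = scalp_potentials([0, 0, 0.8 * head.radius], 10 * u,
                                 cap_positions, head)
    assert np.sqrt((v_shallow**2).mean()) / np.sqrt((v_deep**2).mean()) > 1


def test_average_reference_sums_to_zero(head, cap_positions):
    v = scalp_potentials([10, 5, 40], [3, 4, 5], cap_positions, head)
    assert abs(v.sum()) < 1e-18


def test_source_outside_sphere_rejected(head, cap_positions):
    with pytest.raises(ValueError, match="outside"):
        scalp_potentials([0, 0, head.radius * 1.1], [0, 0, 1], cap_positions,
                         head)


class TestSeegForward:
    def test_axial_value_matches_formula(self):
        # p = 10 nA·m along +z, sigma 0.33, contact 10 mm along +z:
        # V = 1e-10 / (4*pi*0.33*1e-6) ~ 2.411e-5 V
        v = seeg_potentials([0, 0, 0], [0, 0, 10.0], [[0, 0, 10.0]])
        assert v[0] == pytest.approx(1e-10 / (4 * np.pi * 0.33 * 1e-6),
                                     rel=1e-12)

    def test_perpendicular_plane_is_null(self):
        v = seeg_potentials([0, 0, 0], [0, 0, 10.0],
                            [[7.0, -3.0, 0.0], [0.1, 55.0, 0.0]])
        np.testing.assert_allclose(v, 0.0, atol=1e-20)

    def test_inverse_square_on_axis(self):
        v = seeg_potentials([0, 0, 0], [0, 0, 10.0],
                            [[0, 0, 10.0], [0, 0, 20.0]])
        assert v[0] / v[1] == pytest.approx(4.0, rel=1e-12)

    def test_contact_at_source_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            seeg_potentials([1, 2, 3], [0, 0, 1], [[1, 2, 3]])
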