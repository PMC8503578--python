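"""Analytic dipole forward models in a spherical head.

Scalp potentials come from the classic Legendre-series solution for a
current dipole inside a homogeneous conducting sphere with insulating
exterior; SEEG contact potentials use the infinite-homogeneous-medium
dipole potential, appropriate for contacts far from the skull.

Positions are in millimetres, dipole moments in nA·m, conductivity in
S/m, and returned potentials in volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NAM = 1e-9  # nA·m -> A·m
MM = 1e-3  # mm -> m


@dataclass
class HeadModel:
    """Single homogeneous conducting sphere standing in for the head.

    Parameters
    ----------
    center : (3,) array-like
        Sphere centre in mm.
    radius : float
        Scalp-sphere radius in mm.
    conductivity : float
        Homogeneous conductivity in S/m (brain-like 0.33 by default).
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 90.0
    conductivity: float = 0.33

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")

    def eccentricity(self, position) -> float:
        """Relative source depth |pos - center| / radius."""
        return float(np.linalg.norm(np.asarray(position, float) - self.center)
                     / self.radius)


def _legendre_series(cosg: np.ndarray, n_terms: int):
    """P_n(x) and dP_n/dx for n = 1..n_terms, vectorised over x.

    Returns arrays of shape (n_terms, len(x)).
    """
    x = np.asarray(cosg, dtype=float)
    p = np.empty((n_terms + 1,) + x.shape)
    dp = np.empty_like(p)
    p[0] = 1.0
    dp[0] = 0.0
    p[1] = x
    dp[1] = 1.0
    for n in range(2, n_terms + 1):
        p[n] = ((2 * n - 1) * x * p[n - 1] - (n - 1) * p[n - 2]) / n
        dp[n] = dp[n - 2] + (2 * n - 1) * p[n - 1]
    return p[1:], dp[1:]


def _n_terms_for(ecc: float, rtol: float = 1e-12) -> int:
    if ecc < 1e-6:
        return 1
    n = int(np.ceil(np.log(rtol) / np.log(max(ecc, 1e-6))))
    return int(np.clip(n, 12, 1200))


def scalp_potentials(dip_pos, dip_moment, electrode_pos, head: HeadModel,
                     average_reference: bool = True) -> np.ndarray:
    """Surface potentials of a dipole in a homogeneous conducting sphere.

    The solution is the infinite-medium multipole expansion with each
    degree-n harmonic amplified by (2n+1)/n so that no current crosses
    the scalp surface:

        V(R, γ, φ) = 1/(4πσR²) Σ_n (2n+1)/n (b/R)^{n-1}
                     [ n p_r P_n(cos γ) + p_t sin γ cos φ P_n'(cos γ) ]

    with b the source radius, p_r/p_t the radial/tangential moment
    components and γ the angle between electrode and source directions.

    Parameters are in mm / nA·m; the return value is in volts, one entry
    per electrode, average-referenced by default.
    """
    r0 = np.asarray(dip_pos, float) - head.center
    p = np.asarray(dip_moment, float) * NAM
    elec = np.atleast_2d(np.asarray(electrode_pos, float)) - head.center

    R = head.radius * MM
    b = np.linalg.norm(r0) * MM
    ecc = b / R
    if ecc >= 1.0:
        raise ValueError("dipole lies outside the head sphere "
                         f"(eccentricity {ecc:.3f})")

    rhat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    pref = 1.0 / (4 * np.pi * head.conductivity * R**2)

    if b < 1e-9:
        # dipole at the centre: only the n = 1 term survives, V = 3 p·r̂ / 4πσR²
        v = 3.0 * pref * rhat @ p
    else:
        zhat = r0 / np.linalg.norm(r0)
        p_r = float(p @ zhat)
        p_tan_vec = p - p_r * zhat
        p_t = float(np.linalg.norm(p_tan_vec))
        that = p_tan_vec / p_t if p_t > 0 else np.zeros(3)

        cosg = np.clip(rhat @ zhat, -1.0, 1.0)
        singcosf = rhat @ that  # sin γ cos φ in the source frame

        nmax = _n_terms_for(ecc)
        pn, dpn = _legendre_series(cosg, nmax)
        n = np.arange(1, nmax + 1, dtype=float)[:, None]
        tn = np.ones(nmax) if ecc == 0 else ecc ** np.arange(nmax)
        coef = ((2 * n + 1) / n) * tn[:, None]
        v = pref * np.sum(coef * (n * p_r * pn + p_t * singcosf[None, :] * dpn),
                          axis=0)

    if average_reference:
        v = v - v.mean()
    return v


def seeg_potentials(dip_pos, dip_moment, contact_pos,
                    conductivity: float = 0.33) -> np.ndarray:
    """Infinite-homogeneous-medium dipole potential at depth contacts.

    V = p·d / (4πσ|d|³) with d the source→contact vector. Inputs in
    mm / nA·m, output in volts.
    """
    r0 = np.asarray(dip_pos, float)
    p = np.asarray(dip_moment, float) * NAM
    pos = np.atleast_2d(np.asarray(contact_pos, float))
    d = (pos - r0) * MM
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-9):
        raise ValueError("a contact coincides with the source position")
    return (d @ p) / (4 * np.pi * conductivity * dist**3)


def scalp_gain(dip_pos, electrode_pos, head: HeadModel) -> np.ndarray:
    """Average-referenced gain matrix (n_electrodes × 3) for unit moments."""
    return np.column_stack([scalp_potentials(dip_pos, e, electrode_pos, head)
                            for e in np.eye(3)])
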