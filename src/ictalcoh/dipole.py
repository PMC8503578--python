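"""Equivalent current dipole (ECD) fitting in the spherical head model.

Position is found by bounded nonlinear least squares from multiple random
restarts; at every candidate position the moment is the closed-form
linear least-squares solution, so the search runs over 3 spatial
parameters only. Goodness of fit is the percentage of topography
variance explained by the dipole's forward field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import HeadModel, scalp_gain

MAX_ECC = 0.95  # stay clear of the sphere-surface singularity


@dataclass
class DipoleFit:
    position: np.ndarray  # mm
    moment: np.ndarray  # nA·m
    gof: float  # % of topography variance explained
    converged: bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.moment = np.asarray(self.moment, float)


def _residual(topo, pos, electrodes, head):
    g = scalp_gain(pos, electrodes, head)
    q, *_ = np.linalg.lstsq(g, topo, rcond=None)
    return topo - g @ q, q


def fit_ecd(topography, electrodes, head: HeadModel,
            n_restarts: int = 10, seed: int = 0) -> DipoleFit:
    """Fit one dipole to an average-referenced scalp topography.

    Parameters
    ----------
    topography : (n_electrodes,) array
        Component scalp map; re-referenced to average internally.
    electrodes : (n_electrodes, 3) array, mm
    n_restarts : number of uniform-in-sphere initial positions.

    Returns a DipoleFit with position (mm), moment (nA·m per unit
    topography), and GOF in percent.
    """
    from scipy.optimize import least_squares

    topo = np.asarray(topography, float)
    topo = topo - topo.mean()
    electrodes = np.asarray(electrodes, float)
    if len(topo) < 6:
        raise ValueError("need at least 6 electrodes for a dipole fit")
    ss_tot = float(topo @ topo)
    if ss_tot == 0:
        raise ValueError("all-zero topography")

    rng = np.random.default_rng(seed)
    rmax = MAX_ECC * head.radius

    def sph2cart(p):
        r, th, ph = p
        return head.center + r * np.array([
            np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    def fun(p):
        res, _ = _residual(topo, sph2cart(p), electrodes, head)
        return res

    best = None
    n_ok = 0
    for _ in range(n_restarts):
        r0 = rmax * rng.random() ** (1 / 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        x0 = np.array([max(r0, 1.0), np.arccos(np.clip(u[2], -1, 1)),
                       np.arctan2(u[1], u[0])])
        try:
            sol = least_squares(fun, x0,
                                bounds=([0.0, 0.0, -2 * np.pi],
                                        [rmax, np.pi, 2 * np.pi]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        cost = float(sol.cost)
        n_ok += sol.success
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise RuntimeError("all dipole-fit starts failed")
    _, sol = best
    pos = sph2cart(sol.x)
    res, q = _residual(topo, pos, electrodes, head)
    gof = 100.0 * (1.0 - float(res @ res) / ss_tot)
    return DipoleFit(pos, q, max(min(gof, 100.0), 0.0), bool(n_ok > 0))


def fill_gof(decomp, screens, electrodes, head: HeadModel,
             n_restarts: int = 10, seed: int = 0) -> dict:
    """Fit an ECD to every unflagged component; fills screen.gof in place.

    Returns {component id: DipoleFit}.
    """
    fits = {}
    for s in screens:
        if s.outlier_flag:
            continue
        fit = fit_ecd(decomp.mixing[:, s.component], electrodes, head,
                      n_restarts=n_restarts, seed=seed + s.component)
        s.gof = fit.gof
        fits[s.component] = fit
    return fits


def dipoles_to_json(fits: dict, path) -> None:
    import json

    records = [
        {"component": int(c), "x_mm": f.position[0], "y_mm": f.position[1],
         "z_mm": f.position[2], "qx": f.moment[0], "qy": f.moment[1],
         "qz": f.moment[2], "gof": f.gof, "converged": f.converged}
        for c, f in sorted(fits.items())
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
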