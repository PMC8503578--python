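"""Dipole-to-contact distance profiles, SOZ localization error, correlations.

All coordinates are assumed co-registered in one mm frame ("MNI-like");
no registration is performed here. Distances to SEEG bipolar pairs are
measured to the pair's geometric midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SOZDefinition:
    """Seizure-onset-zone contacts and their geometric centre."""

    labels: list
    center: np.ndarray

    @classmethod
    def from_contacts(cls, labels, coords: dict) -> "SOZDefinition":
        labels = list(labels)
        if not labels:
            raise ValueError("SOZ needs at least one contact")
        pts = np.array([coords[lab] for lab in labels], float)
        return cls(labels, pts.mean(axis=0))


@dataclass
class SpatialSummary:
    pair_labels: list
    distances_mm: np.ndarray
    sna: np.ndarray
    max_coh_pair: str
    max_coh_distance_mm: float
    d_soz_mm: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def pair_midpoint(contact_a, contact_b) -> np.ndarray:
    """Geometric midpoint of a bipolar contact pair (componentwise mean)."""
    return 0.5 * (np.asarray(contact_a, float) + np.asarray(contact_b, float))


def distance_profile(dipole_pos, pair_midpoints: dict):
    """Euclidean dipole-to-pair distances (mm).

    Returns (labels, distances); pairs with missing coordinates are
    skipped with a warning.
    """
    d = np.asarray(dipole_pos, float)
    labels, dists = [], []
    for lab, mid in pair_midpoints.items():
        if mid is None or np.any(~np.isfinite(np.asarray(mid, float))):
            warnings.warn(f"pair {lab}: missing coordinates, skipped")
            continue
        labels.append(lab)
        dists.append(float(np.linalg.norm(d - np.asarray(mid, float))))
    return labels, np.array(dists)


def soz_error(dipole_pos, soz: SOZDefinition) -> float:
    """Euclidean distance from the dipole to the SOZ geometric centre, mm."""
    return float(np.linalg.norm(np.asarray(dipole_pos, float) - soz.center))


def coherence_distance_correlation(sna, distances):
    """Pearson and Spearman correlation between coherence and distance.

    Returns (r, p_r, rho, p_rho); NaNs (with a warning) when either
    variable is constant.
    """
    from scipy import stats

    sna = np.asarray(sna, float)
    distances = np.asarray(distances, float)
    if sna.size != distances.size or sna.size < 3:
        raise ValueError("need >= 3 matched (coherence, distance) pairs")
    if np.ptp(sna) == 0 or np.ptp(distances) == 0:
        warnings.warn("zero variance; correlation undefined")
        return np.nan, np.nan, np.nan, np.nan
    pr = stats.pearsonr(sna, distances)
    sr = stats.spearmanr(sna, distances)
    return (float(pr.statistic), float(pr.pvalue),
            float(sr.statistic), float(sr.pvalue))


def lowess_smooth(x, y, span: float = 0.7) -> np.ndarray:
    """Tricube-weighted local linear smoothing evaluated at the sample x's.

    Display-layer companion to the coherence/distance scatter. Returns
    fitted values aligned with the input order.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if x.size < 5:
        raise ValueError("need at least 5 points")
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted, float)


def spatial_summary(dipole_pos, pair_midpoints: dict, pair_sna: dict,
                    soz: SOZDefinition | None = None) -> SpatialSummary:
    """Assemble the distance/coherence profile for one component dipole."""
    labels, dists = distance_profile(dipole_pos, pair_midpoints)
    sna = np.array([pair_sna[lab] for lab in labels])
    imax = int(np.argmax(sna))
    if len(labels) >= 3 and np.ptp(sna) > 0 and np.ptp(dists) > 0:
        r, pr, rho, prho = coherence_distance_correlation(sna, dists)
    else:
        r = pr = rho = prho = np.nan
    return SpatialSummary(
        pair_labels=labels, distances_mm=dists, sna=sna,
        max_coh_pair=labels[imax], max_coh_distance_mm=float(dists[imax]),
        d_soz_mm=soz_error(dipole_pos, soz) if soz is not None else np.nan,
        pearson_r=r, pearson_p=pr, spearman_rho=rho, spearman_p=prho)
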