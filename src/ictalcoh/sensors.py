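"""Electrode geometry: scalp caps on the model sphere and SEEG depth shafts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import HeadModel

# Reduced 10-20 set used for the default cap. Real long-term monitoring caps
# in the simulated setting have 20-37 electrodes with gaps where depth-electrode
# anchors interfere; `drop` emulates the missing positions.
DEFAULT_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "FCz",
]

TEMPORAL_LABELS = {"F7", "F8", "T7", "T8", "P7", "P8"}


@dataclass
class Shaft:
    """One SEEG depth electrode: collinear contacts at fixed pitch."""

    label: str
    contacts: list  # list of (label, (3,) position mm)

    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.contacts], dtype=float)

    def labels(self) -> list:
        return [lab for lab, _ in self.contacts]


@dataclass
class SensorArray:
    """Scalp electrodes plus SEEG shafts, all in one mm coordinate frame."""

    scalp: list = field(default_factory=list)  # (label, (3,) mm)
    shafts: list = field(default_factory=list)  # Shaft

    def __post_init__(self) -> None:
        labels = self.scalp_labels() + self.seeg_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("sensor labels must be unique")

    def scalp_labels(self) -> list:
        return [lab for lab, _ in self.scalp]

    def scalp_positions(self) -> np.ndarray:
        return np.array([p for _, p in self.scalp], dtype=float)

    def seeg_labels(self) -> list:
        return [lab for sh in self.shafts for lab in sh.labels()]

    def seeg_positions(self) -> np.ndarray:
        return np.vstack([sh.positions() for sh in self.shafts])

    def coordinates(self) -> dict:
        """label -> (3,) mm position for every sensor."""
        out = {lab: np.asarray(p, float) for lab, p in self.scalp}
        for sh in self.shafts:
            for lab, p in sh.contacts:
                out[lab] = np.asarray(p, float)
        return out

    def validate(self, head: HeadModel, pitch: float = 3.5,
                 tol: float = 1e-6) -> None:
        """Check geometry: electrodes on the sphere, shafts collinear."""
        pos = self.scalp_positions()
        r = np.linalg.norm(pos - head.center, axis=1)
        if not np.allclose(r, head.radius, atol=tol):
            raise ValueError("scalp electrodes must lie on the sphere surface")
        if not (2 <= len(self.seeg_labels()) <= 258):
            raise ValueError("2-258 SEEG contacts supported")
        for sh in self.shafts:
            p = sh.positions()
            if len(p) < 2:
                continue
            d = np.diff(p, axis=0)
            step = np.linalg.norm(d, axis=1)
            if not np.allclose(step, pitch, atol=1e-3):
                raise ValueError(f"shaft {sh.label}: contact pitch != {pitch} mm")
            u = d / step[:, None]
            if not np.allclose(u, u[0], atol=1e-6):
                raise ValueError(f"shaft {sh.label}: contacts not collinear")


def standard_scalp_cap(head: HeadModel, labels=None, drop=()) -> list:
    """Spherical projection of a reduced 10-20 cap.

    Uses mne's standard_1020 template positions, recentred and radially
    projected onto the model sphere. `drop` removes electrodes that could
    not be placed (depth-electrode anchors in the emulated setting).
    """
    import mne

    labels = list(labels or DEFAULT_1020)
    labels = [lab for lab in labels if lab not in set(drop)]
    try:
        mont = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older template name
        mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    out = []
    for lab in labels:
        p = np.asarray(pos[lab], float)
        p = p / np.linalg.norm(p) * head.radius + head.center
        out.append((lab, p))
    return out


def make_shaft(label: str, tip: np.ndarray, direction: np.ndarray,
               n_contacts: int, pitch: float = 3.5,
               start_index: int = 1) -> Shaft:
    """Build a depth shaft from its deepest contact outward along `direction`."""
    if not 1 <= n_contacts <= 18:
        raise ValueError("depth electrodes carry 1-18 contacts")
    tip = np.asarray(tip, float)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    contacts = [(f"{label}{start_index + k:02d}", tip + k * pitch * u)
                for k in range(n_contacts)]
    return Shaft(label=label, contacts=contacts)
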