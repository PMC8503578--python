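"""Recording container and EDF / BrainVision file I/O.

EEG data are held in microvolts, channels x samples. Channel roles
(scalp, seeg, trigger, refsine) are encoded in EDF labels via a prefix
convention ("EEG Fz", "SEEG V01", "TRIG", "SINE") so that a session
round-trips through plain EDF files.

Reading goes through mne (EDF and BrainVision); writing uses a minimal
16-bit EDF writer with 1-second data records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CH_SCALP = "scalp"
CH_SEEG = "seeg"
CH_TRIGGER = "trigger"
CH_REFSINE = "refsine"
CH_OTHER = "other"

_PREFIX = {CH_SCALP: "EEG ", CH_SEEG: "SEEG ", CH_TRIGGER: "TRIG",
           CH_REFSINE: "SINE", CH_OTHER: ""}


@dataclass
class Recording:
    """Labelled multichannel time series from one amplifier.

    data : (n_channels, n_samples) float array in µV
    channel_types : per-channel role, one of scalp/seeg/trigger/refsine/other
    start_offset : recording start relative to the session clock, s
    """

    data: np.ndarray
    labels: list
    fs: float
    channel_types: list
    start_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.labels) == 0:
            raise ValueError("a Recording needs at least one channel")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must match data rows "
                             f"({len(self.labels)} vs {self.data.shape[0]})")
        if len(self.channel_types) != len(self.labels):
            raise ValueError("channel_types must match labels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("NaN values in recording data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.n_samples) / self.fs

    def pick(self, ctype: str) -> "Recording":
        """Sub-recording with only channels of the given role."""
        idx = [i for i, t in enumerate(self.channel_types) if t == ctype]
        if not idx:
            raise ValueError(f"no channels of type {ctype!r}")
        return Recording(self.data[idx], [self.labels[i] for i in idx],
                         self.fs, [ctype] * len(idx), self.start_offset,
                         dict(self.meta))

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


def _edf_label(label: str, ctype: str) -> str:
    if ctype in (CH_TRIGGER, CH_REFSINE):
        # trigger/sine labels already carry their role marker
        prefix = _PREFIX[ctype]
        return (label if label.startswith(prefix)
                else prefix + " " + label)[:16]
    return (_PREFIX.get(ctype, "") + label)[:16]


def _parse_edf_label(raw_label: str):
    s = raw_label.strip()
    if s.startswith("SEEG "):
        return s[5:], CH_SEEG
    if s.startswith("EEG "):
        return s[4:], CH_SCALP
    if s.startswith("TRIG"):
        return s, CH_TRIGGER
    if s.startswith("SINE"):
        return s, CH_REFSINE
    return s, CH_OTHER


def write_recording(rec: Recording, path) -> None:
    """Write a Recording to 16-bit EDF with 1-second data records."""
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = rec.data
    nch, nsamp = data.shape
    nrec = int(np.ceil(nsamp / spr))
    pad = nrec * spr - nsamp
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax <= pmin
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    def fix(s, n):
        b = str(s).encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        fix("0", 8), fix("X X X X", 80), fix("Startdate X X X X", 80),
        fix("01.01.20", 8), fix("00.00.00", 8), fix(256 * (nch + 1), 8),
        fix("", 44), fix(nrec, 8), fix("1", 8), fix(nch, 4),
    ])
    labels = [_edf_label(lab, ct) for lab, ct in zip(rec.labels,
                                                     rec.channel_types)]
    for func, n in [
        (lambda i: labels[i], 16), (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: "%.10g" % pmin[i], 8), (lambda i: "%.10g" % pmax[i], 8),
        (lambda i: dmin, 8), (lambda i: dmax, 8),
        (lambda i: "", 80), (lambda i: spr, 8), (lambda i: "", 32),
    ]:
        hdr += b"".join(fix(func(i), n) for i in range(nch))

    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((data - pmin[:, None]) * scale[:, None]
                   + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            fh.write(np.ascontiguousarray(
                dig[:, r * spr:(r + 1) * spr]).tobytes())


def read_recording(path) -> Recording:
    """Read an EDF or BrainVision (.vhdr) file into a Recording."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".vhdr":
        _check_brainvision_triplet(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if path.suffix.lower() == ".edf":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            elif path.suffix.lower() == ".vhdr":
                raw = mne.io.read_raw_brainvision(path, preload=True,
                                                  verbose="error")
            else:
                raise ValueError(f"unsupported recording format: {path.suffix}")
    except ValueError:
        raise
    except Exception as err:  # noqa: BLE001 - re-raise with file context
        raise OSError(f"failed to parse {path.name}: {err}") from err

    data = raw.get_data() * 1e6  # mne returns volts for EEG-dim channels
    labels, types = [], []
    for raw_label in raw.ch_names:
        lab, ct = _parse_edf_label(raw_label)
        labels.append(lab)
        types.append(ct)
    rec = Recording(data, labels, float(raw.info["sfreq"]), types)
    if np.isnan(rec.data).any():
        raise OSError(f"NaN samples after reading {path.name}")
    return rec


_BV_SAMPLE_BYTES = {"IEEE_FLOAT_32": 4, "INT_16": 2, "INT_32": 4}


def _check_brainvision_triplet(vhdr: Path) -> None:
    """Validate that the binary payload divides evenly across channels."""
    import re

    text = vhdr.read_text(errors="replace")

    def field(name, default=None):
        m = re.search(rf"^{name}=(.+)$", text, re.MULTILINE)
        return m.group(1).strip() if m else default

    datafile = field("DataFile")
    nchan = field("NumberOfChannels")
    fmt = field("BinaryFormat", "IEEE_FLOAT_32")
    if datafile is None or nchan is None:
        raise OSError(f"{vhdr.name}: missing DataFile/NumberOfChannels")
    eeg = vhdr.parent / datafile
    if not eeg.exists():
        raise OSError(f"{vhdr.name}: data file {datafile} not found")
    frame = int(nchan) * _BV_SAMPLE_BYTES.get(fmt, 4)
    size = eeg.stat().st_size
    if size % frame != 0:
        raise OSError(
            f"{vhdr.name}: {size} bytes is not a whole number of "
            f"{int(nchan)}-channel frames — sample counts are inconsistent")


def write_coordinates_tsv(sensors, path) -> None:
    """Write sensor coordinates as TSV: label, x_mm, y_mm, z_mm, type."""
    import pandas as pd

    rows = [(lab, *pos, CH_SCALP) for lab, pos in sensors.scalp]
    for sh in sensors.shafts:
        rows += [(lab, *pos, CH_SEEG) for lab, pos in sh.contacts]
    df = pd.DataFrame(rows, columns=["label", "x_mm", "y_mm", "z_mm", "type"])
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_coordinates_tsv(path) -> dict:
    """Read a coordinates TSV into {label: (3,) mm array}."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(r.label): np.array([r.x_mm, r.y_mm, r.z_mm], float)
            for r in df.itertuples()}
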