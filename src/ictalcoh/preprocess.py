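"""Band-pass filtering, SEEG bipolar re-referencing, ictal epoch extraction."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io import CH_SEEG, Recording


@dataclass
class FilterSpec:
    """Hamming windowed-sinc FIR band-pass (default 5-100 Hz, 2 Hz transition)."""

    band: tuple = (5.0, 100.0)
    transition: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("need 0 < low < high")
        if self.transition <= 0:
            raise ValueError("transition must be positive")

    def numtaps(self, fs: float) -> int:
        # Hamming design rule: transition width ~ 3.3/N * fs
        n = int(np.ceil(3.3 / self.transition * fs))
        return n + 1 - n % 2  # odd, so the filter is symmetric around a tap


@dataclass
class EpochSpec:
    """Analysis epoch around the seizure-onset (SO) marker: [-pre, +post] s."""

    so_marker: float
    pre: float = 20.0
    post: float = 10.0

    def __post_init__(self) -> None:
        if self.pre <= 0 or self.post <= 0:
            raise ValueError("pre and post must be positive")


def fir_taps(spec: FilterSpec, fs: float) -> np.ndarray:
    from scipy.signal import firwin

    lo, hi = spec.band
    if hi + spec.transition / 2 >= fs / 2:
        raise ValueError(f"band {spec.band} does not fit below Nyquist "
                         f"({fs / 2} Hz) with a {spec.transition} Hz transition")
    # -6 dB cutoffs at band edge minus half the transition width, so the
    # passband edge itself sits at full amplitude
    return firwin(spec.numtaps(fs),
                  [lo - spec.transition / 2, hi + spec.transition / 2],
                  window="hamming", pass_zero=False, fs=fs)


def bandpass_fir(rec: Recording, spec: FilterSpec | None = None,
                 skip_types=("trigger", "refsine")) -> Recording:
    """Zero-phase band-pass: symmetric FIR applied with centred convolution.

    A symmetric odd-length kernel applied via "same"-mode convolution is
    exactly zero-phase, matching forward filtering with group-delay
    compensation. Trigger and reference-sine channels pass through
    untouched.
    """
    from scipy.signal import fftconvolve

    spec = spec or FilterSpec()
    taps = fir_taps(spec, rec.fs)
    out = rec.data.copy()
    for i, ctype in enumerate(rec.channel_types):
        if ctype in skip_types:
            continue
        out[i] = fftconvolve(rec.data[i], taps, mode="same")
    return Recording(out, list(rec.labels), rec.fs, list(rec.channel_types),
                     rec.start_offset, dict(rec.meta))


_LABEL_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


def bipolar_montage(rec: Recording, coords: dict | None = None) -> Recording:
    """Re-reference SEEG channels to consecutive same-shaft differences.

    Contacts must be labelled shaft+index (V01...V18). The output contains
    one channel per adjacent same-shaft pair, labelled "V01-V02"; pairs
    never straddle shafts. If `coords` (label -> mm position) is given,
    pair geometric midpoints are stored in meta["pair_midpoints"] for the
    spatial analysis.
    """
    idx = [i for i, t in enumerate(rec.channel_types) if t == CH_SEEG]
    if not idx:
        raise ValueError("no SEEG channels to re-reference")
    parsed = []
    for i in idx:
        m = _LABEL_RE.match(rec.labels[i])
        if not m:
            raise ValueError(f"cannot parse SEEG label {rec.labels[i]!r} "
                             "as shaft+index")
        parsed.append((m.group(1), int(m.group(2)), i))

    rows, labels, midpoints = [], [], {}
    for (sh_a, k_a, i_a), (sh_b, k_b, i_b) in zip(parsed[:-1], parsed[1:]):
        if sh_a != sh_b or k_b != k_a + 1:
            continue
        lab = f"{rec.labels[i_a]}-{rec.labels[i_b]}"
        rows.append(rec.data[i_a] - rec.data[i_b])
        labels.append(lab)
        if coords is not None:
            midpoints[lab] = 0.5 * (np.asarray(coords[rec.labels[i_a]], float)
                                    + np.asarray(coords[rec.labels[i_b]],
                                                 float))
    meta = dict(rec.meta)
    if coords is not None:
        meta["pair_midpoints"] = midpoints
    return Recording(np.array(rows), labels, rec.fs, [CH_SEEG] * len(labels),
                     rec.start_offset, meta)


def extract_epoch(rec: Recording, spec: EpochSpec) -> Recording:
    """Cut the [-pre, +post] window around SO; time re-zeroed to epoch start."""
    t0 = spec.so_marker - spec.pre
    t1 = spec.so_marker + spec.post
    if t0 < rec.start_offset - 1e-9 or \
            t1 > rec.start_offset + rec.n_samples / rec.fs + 1e-9:
        raise ValueError(
            f"epoch [{t0}, {t1}] s falls outside the recording span")
    i0 = int(round((t0 - rec.start_offset) * rec.fs))
    n = int(round((spec.pre + spec.post) * rec.fs))
    if i0 + n > rec.n_samples:
        raise ValueError("epoch extends past the end of the recording")
    meta = dict(rec.meta)
    meta["so_in_epoch_s"] = spec.pre
    return Recording(rec.data[:, i0:i0 + n].copy(), list(rec.labels), rec.fs,
                     list(rec.channel_types), 0.0, meta)
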