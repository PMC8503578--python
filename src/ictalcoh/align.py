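"""Align two independently clocked streams: triggers coarse, 50 Hz sine fine.

The shared periodic trigger pulses resolve the alignment to the sample
(and disambiguate the reference sine, which is only informative modulo
its period); windowed cross-correlation of the 50 Hz reference sine with
parabolic peak interpolation then refines each trigger's lag to a
fraction of a sample. Clock drift is the slope of the per-trigger lag
over time, and merging resamples stream b onto stream a's clock with a
piecewise-linear time map between trigger pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CH_REFSINE, CH_TRIGGER, Recording


@dataclass
class AlignmentResult:
    """Lag of stream b relative to stream a, in stream-a samples."""

    coarse_lag: int
    fine_lag: float
    drift_ppm: float
    residual: float  # worst per-trigger deviation from the linear lag model
    fine_available: bool = True
    trigger_map: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def lag_at(self, a_index) -> np.ndarray:
        """Interpolated lag (samples) at arbitrary stream-a sample indices."""
        m = self.trigger_map
        if len(m) == 0:
            return np.full(np.shape(a_index), float(self.fine_lag))
        if len(m) == 1:
            return np.full(np.shape(a_index), m[0, 0] - m[0, 1])
        lags = m[:, 0] - m[:, 1]
        out = np.interp(a_index, m[:, 0], lags)
        # linear extrapolation beyond the first/last trigger
        a = np.asarray(a_index, float)
        s0 = (lags[1] - lags[0]) / (m[1, 0] - m[0, 0])
        s1 = (lags[-1] - lags[-2]) / (m[-1, 0] - m[-2, 0])
        out = np.where(a < m[0, 0], lags[0] + s0 * (a - m[0, 0]), out)
        out = np.where(a > m[-1, 0], lags[-1] + s1 * (a - m[-1, 0]), out)
        return out


def trigger_onsets(rec: Recording) -> np.ndarray:
    """Sample indices of trigger-pulse rising edges (half-max threshold)."""
    x = rec.pick(CH_TRIGGER).data[0]
    if x.max() <= 0:
        return np.array([], dtype=int)
    hi = x > 0.5 * x.max()
    edges = np.flatnonzero(hi[1:] & ~hi[:-1]) + 1
    # a pulse already high at sample 0 is truncated: not a usable onset
    return edges


def _match_onsets(on_a: np.ndarray, on_b: np.ndarray):
    """Pair trigger onsets across streams allowing missed leading pulses."""
    best = None
    tol = 0.1 * np.median(np.diff(on_a)) if len(on_a) > 1 else np.inf
    for ka in range(len(on_a)):
        for kb in range(len(on_b)):
            m = min(len(on_a) - ka, len(on_b) - kb)
            if m < 2:
                continue
            d = on_a[ka:ka + m] - on_b[kb:kb + m]
            spread = d.max() - d.min()
            # true pairings have near-constant offset (drift is tiny); with
            # periodic pulses the index pairing is ambiguous modulo the
            # interval, so prefer the smallest lag (inter-amplifier lags are
            # far below the trigger interval in practice)
            if spread < tol:
                score = (-m, abs(float(np.median(d))), spread)
                if best is None or score < best[0]:
                    best = (score, ka, kb, m)
    if best is None:
        raise ValueError("fewer than 2 matching trigger pulses")
    _, ka, kb, m = best
    return on_a[ka:ka + m], on_b[kb:kb + m]


def _sine_refine(sa: np.ndarray, sb: np.ndarray, center_a: int,
                 int_lag: int, fs: float, sine_freq: float,
                 window_s: float = 2.0) -> float:
    """Refine one trigger's lag via windowed cross-correlation of the sine.

    Searches ± half a sine period around the integer trigger lag and
    interpolates the correlation peak parabolically, then polishes the
    sub-sample offset with a few Newton steps on a local cosine model of
    the correlation function (the correlation of two windowed sines is
    locally sinusoidal, which the three-point parabola only approximates).
    """
    half = int(round(window_s * fs / 2))
    period = fs / sine_freq
    search = int(np.ceil(period / 2)) + 1
    a0, a1 = center_a - half, center_a + half
    b0 = a0 - int_lag - search
    b1 = a1 - int_lag + search
    if a0 < 0 or a1 > len(sa) or b0 < 0 or b1 > len(sb):
        return np.nan
    seg_a = sa[a0:a1]
    seg_b = sb[b0:b1]
    from scipy.signal import correlate

    c = correlate(seg_a, seg_b, mode="valid")  # index s: b shifted by s-search
    k = int(np.argmax(c))
    if k == 0 or k == len(c) - 1:
        return np.nan
    # parabolic first guess
    y0, y1, y2 = c[k - 1], c[k], c[k + 1]
    denom = (y0 - 2 * y1 + y2)
    frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    # cosine polish: near its peak the correlation of two windowed sines is
    # A cos(w s)+B sin(w s) with w = 2πf/fs; fit through the 3 points and
    # take the analytic extremum (the parabola alone is biased at this
    # coarse sampling of the 50 Hz cycle)
    w = 2 * np.pi * sine_freq / fs
    s_pts = np.array([-1.0, 0.0, 1.0])
    M = np.column_stack([np.cos(w * s_pts), np.sin(w * s_pts)])
    ab, *_ = np.linalg.lstsq(M, np.array([y0, y1, y2]), rcond=None)
    frac_cos = np.arctan2(ab[1], ab[0]) / w
    if abs(frac_cos) <= 1.0:
        frac = frac_cos
    # scipy's valid-mode correlate gives c[s] = sum_t seg_a[t]*seg_b[t+S-s]
    # with S = len(seg_b)-len(seg_a) = 2*search; the peak s* satisfies
    # b0+t+S-s* == (a0+t)-L, hence L = (a0-b0) - 2*search + s*
    return float((a0 - b0) - 2 * search + (k + frac))


def align_streams(a: Recording, b: Recording,
                  sine_freq: float = 50.0,
                  window_s: float = 2.0) -> AlignmentResult:
    """Estimate the lag/drift of stream b relative to stream a.

    fine_lag is the lag at stream-a time zero, expressed in stream-a
    (master-clock) samples; drift_ppm is the relative clock-rate error of
    stream b.
    """
    if a.fs != b.fs:
        raise ValueError("streams must share a sampling rate")
    fs = a.fs
    on_a, on_b = _match_onsets(trigger_onsets(a), trigger_onsets(b))

    d = on_a - on_b
    coarse_lag = int(np.median(d))

    try:
        sine_a = a.pick(CH_REFSINE).data[0]
        sine_b = b.pick(CH_REFSINE).data[0]
    except ValueError:
        warnings.warn("reference sine absent; coarse alignment only")
        t = on_a / fs
        slope = np.polyfit(t, d.astype(float), 1)[0] if len(d) > 2 else 0.0
        return AlignmentResult(coarse_lag, float(coarse_lag),
                               slope / fs * 1e6, float(np.ptp(d)),
                               fine_available=False,
                               trigger_map=np.column_stack(
                                   [on_a, on_a - d]).astype(float))

    fine = []
    kept_a = []
    for oa, di in zip(on_a, d):
        lag_i = _sine_refine(sine_a, sine_b, int(oa), int(di), fs, sine_freq,
                             window_s)
        if np.isfinite(lag_i):
            fine.append(lag_i)
            kept_a.append(oa)
    if len(fine) < 2:
        raise ValueError("fewer than 2 triggers usable for fine alignment")
    fine = np.asarray(fine)
    kept_a = np.asarray(kept_a, float)

    t = kept_a / fs
    slope, intercept = np.polyfit(t, fine, 1)
    drift_ppm = slope / fs * 1e6
    delta = drift_ppm * 1e-6
    fine_lag = intercept * (1 + delta)  # back to master-clock samples
    pred = intercept + slope * t
    residual = float(np.abs(fine - pred).max())
    if abs(fine_lag - coarse_lag) > fs / sine_freq / 2:
        warnings.warn("fine lag moved more than half a sine period from the "
                      "trigger estimate; check the reference sine")
    return AlignmentResult(coarse_lag, float(fine_lag), float(drift_ppm),
                           residual, True,
                           trigger_map=np.column_stack(
                               [kept_a, kept_a - fine]))


def merge_streams(a: Recording, b: Recording,
                  alignment: AlignmentResult) -> Recording:
    """Resample stream b onto stream a's clock and concatenate channels.

    Only the overlapping span is kept. Stream-b channels are cubic-spline
    interpolated at the piecewise-linear time map defined by the aligned
    trigger pairs (constant-lag fallback when triggers are unavailable).
    """
    from scipy.interpolate import CubicSpline

    if a.fs != b.fs:
        raise ValueError("streams must share a sampling rate")
    j = np.arange(a.n_samples, dtype=float)
    b_idx = j - alignment.lag_at(j)
    valid = (b_idx >= 0) & (b_idx <= b.n_samples - 1)
    if not valid.any():
        raise ValueError("streams do not overlap after alignment")
    j = j[valid].astype(int)
    b_idx = b_idx[valid]

    spline = CubicSpline(np.arange(b.n_samples), b.data, axis=1)
    b_resampled = spline(b_idx)

    labels = list(a.labels) + [lab if lab not in a.labels else lab + "_b"
                               for lab in b.labels]
    data = np.vstack([a.data[:, j], b_resampled])
    return Recording(data, labels, a.fs,
                     list(a.channel_types) + list(b.channel_types),
                     start_offset=a.start_offset + j[0] / a.fs,
                     meta={"alignment": alignment})
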