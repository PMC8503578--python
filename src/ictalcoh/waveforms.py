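"""Seizure-onset waveform patterns emitted by the simulated ictal generator.

Patterns mirror the onset morphologies seen in depth recordings of focal
seizures: low-voltage fast activity (LVFA, narrowband 30-80 Hz), bursts of
polyspikes, ~10 Hz repetitive sharp discharges, and sporadic preictal
spikes. All are unit-scale moment time courses; physical amplitude comes
from the source's dipole moment.
"""

from __future__ import annotations

import numpy as np

PATTERNS = ("lvfa", "polyspike_burst", "repetitive_discharge",
            "preictal_spikes")


def _spike(fs: float, width_s: float = 0.06) -> np.ndarray:
    """Biphasic sharp transient (Gaussian first derivative), peak ~1."""
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    s = -t / width_s * np.exp(0.5 - (t / width_s) ** 2 / 2)
    return s / np.abs(s).max()


def _add_at(x: np.ndarray, kernel: np.ndarray, center: int,
            amp: float) -> None:
    half = len(kernel) // 2
    lo, hi = center - half, center + half + 1
    klo, khi = max(0, -lo), len(kernel) - max(0, hi - len(x))
    lo, hi = max(lo, 0), min(hi, len(x))
    if lo < hi:
        x[lo:hi] += amp * kernel[klo:khi]


def synth_ictal_waveform(pattern: str, characteristic_frequency: float,
                         onset_time: float, duration: float, fs: float,
                         seed: int = 0, amplitude: float = 1.0,
                         n_samples: int | None = None) -> np.ndarray:
    """Generate one ictal-pattern moment time course.

    Parameters
    ----------
    pattern : {"lvfa", "polyspike_burst", "repetitive_discharge", "preictal_spikes"}
    characteristic_frequency : Hz
        Oscillation / discharge rate of the pattern.
    onset_time : s
        Seizure-onset instant; the waveform is ~0 before it except for the
        preictal_spikes pattern.
    amplitude : unitless scale; 0 gives an all-zero waveform.
    n_samples : optional explicit length (defaults to round(duration*fs)).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; one of {PATTERNS}")
    if onset_time >= duration:
        raise ValueError("onset_time must precede the end of the record")
    n = int(round(duration * fs)) if n_samples is None else int(n_samples)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.zeros(n)
    if amplitude == 0:
        return x
    on = t >= onset_time

    if pattern == "lvfa":
        # narrowband fast oscillation: ~1 s amplitude ramp, slow envelope
        # fluctuation and a small phase random walk to de-idealise the line
        ramp = np.clip((t - onset_time) / 1.0, 0, 1) * on
        env_noise = rng.normal(size=n)
        from scipy.ndimage import gaussian_filter1d
        env = 1.0 + 0.3 * gaussian_filter1d(env_noise, sigma=fs * 0.5)
        phase_rw = np.cumsum(rng.normal(scale=0.02, size=n))
        x = ramp * env * np.sin(2 * np.pi * characteristic_frequency * t
                                + phase_rw)
    elif pattern == "repetitive_discharge":
        period = 1.0 / characteristic_frequency
        k = _spike(fs, width_s=min(0.05, 0.3 * period))
        t_sp = onset_time + 0.2
        while t_sp < duration:
            _add_at(x, k, int(round(t_sp * fs)), 1.0 + 0.2 * rng.normal())
            t_sp += period
    elif pattern == "polyspike_burst":
        k = _spike(fs, width_s=0.04)
        t_burst = onset_time + 0.3
        while t_burst < duration:
            n_sp = rng.integers(3, 7)
            for j in range(n_sp):
                c = t_burst + j / 20.0  # intra-burst polyspikes at ~20 Hz
                _add_at(x, k, int(round(c * fs)), 0.8 + 0.4 * rng.random())
            t_burst += 1.2 + 0.4 * rng.random()
    elif pattern == "preictal_spikes":
        k = _spike(fs, width_s=0.07)
        t_sp = 0.5 + rng.exponential(1.2)
        while t_sp < duration:
            _add_at(x, k, int(round(t_sp * fs)), 0.7 + 0.6 * rng.random())
            t_sp += 0.4 + rng.exponential(1.2)

    return amplitude * x
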