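"""Simulate simultaneous scalp / SEEG sessions with a known ictal generator.

Two galvanically independent amplifiers are emulated: both see the same
physical sources (one ictal dipole plus spatially distributed 1/f
background generators), but the depth stream may start late by an imposed
lag and run on a slightly detuned clock (ppm drift). Both streams carry a
digital trigger channel (shared periodic pulses) and a 50 Hz reference
sine, which downstream alignment uses to re-synchronise them. Muscle
(EMG) noise contaminates temporal scalp channels only — depth contacts
referenced intracranially are EMG-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as icio
from .sensors import TEMPORAL_LABELS, SensorArray, make_shaft, \
    standard_scalp_cap
from .sphere import HeadModel, scalp_potentials, seeg_potentials
from .waveforms import PATTERNS, synth_ictal_waveform

V_TO_UV = 1e6

_PATTERN_BANDS = {"lvfa": (30.0, 80.0), "repetitive_discharge": (5.0, 15.0),
                  "polyspike_burst": (2.0, 30.0), "preictal_spikes": (0.1, 5.0)}


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(a @ b)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


@dataclass
class SourceSpec:
    """One ictal generator: where, which way, what it emits.

    `extent_mm` > 0 models an extended synchronous cortical patch as a
    disc of sub-dipoles (total moment preserved) on the source's depth
    shell — scalp-visible ictal generators are patches of several cm²,
    not points, and the patch broadens the scalp topography accordingly.
    """

    position: np.ndarray
    orientation: np.ndarray
    pattern: str
    characteristic_frequency: float
    onset_time: float
    amplitude: float  # total dipole moment, nA·m
    extent_mm: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.orientation = np.asarray(self.orientation, float)
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("orientation must be a unit vector")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        lo, hi = _PATTERN_BANDS[self.pattern]
        if not lo <= self.characteristic_frequency <= hi:
            raise ValueError(
                f"{self.pattern} frequency {self.characteristic_frequency} Hz "
                f"outside plausible band [{lo}, {hi}]")

    def moment(self) -> np.ndarray:
        return self.amplitude * self.orientation

    def subsources(self, center=None):
        """(position, moment) per sub-dipole of the patch.

        A point source returns itself. A patch is sampled at 13 points
        (centre + two rings) on the sphere shell through the source,
        each sub-moment parallel-transported from the central
        orientation, with the total moment split equally.
        """
        if self.extent_mm <= 0:
            return [(self.position, self.moment())]
        c = np.zeros(3) if center is None else np.asarray(center, float)
        r0 = self.position - c
        b = np.linalg.norm(r0)
        u = r0 / b
        e1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-9:
            e1 = np.cross(u, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        offsets = [(0.0, 0.0)]
        for frac, npts in [(0.5, 4), (1.0, 8)]:
            for j in range(npts):
                ang = 2 * np.pi * j / npts
                offsets.append((frac * self.extent_mm * np.cos(ang),
                                frac * self.extent_mm * np.sin(ang)))
        out = []
        q = self.moment() / len(offsets)
        for dx, dy in offsets:
            d = u * b + e1 * dx + e2 * dy
            d = d / np.linalg.norm(d) * b  # back onto the depth shell
            rot = _rotation_between(u, d / b)
            out.append((c + d, rot @ q))
        return out


@dataclass
class SimulationConfig:
    """Session-level knobs. Desk-scale defaults: 512 Hz, 60 s, 10 s triggers."""

    fs: float = 512.0
    duration: float = 60.0
    n_background_sources: int = 200
    background_exponent: float = 1.0
    background_amplitude: float = 11.0  # nA·m per background source
    emg_level: float = 4.0  # µV RMS on temporal scalp channels
    sensor_noise: float = 2.0  # µV RMS white noise, both streams
    clock_drift_ppm: float = 0.0
    trigger_interval: float = 10.0
    ref_sine_freq: float = 50.0
    imposed_lag: float = 0.0  # samples, may be fractional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 30.0:
            raise ValueError("duration must be at least 30 s")
        if self.fs <= 0 or self.trigger_interval <= 0:
            raise ValueError("fs and trigger_interval must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the pipeline."""

    source: SourceSpec
    scalp_mixing: np.ndarray  # true average-referenced scalp column, µV
    soz_labels: list
    imposed_lag: float
    clock_drift_ppm: float
    trigger_times: np.ndarray

    def soz_bipolar_label(self) -> str:
        a, b = self.soz_labels[0], self.soz_labels[1]
        return f"{a}-{b}"


def _source_scalp_gain(src: SourceSpec, scalp_pos, head: HeadModel
                       ) -> np.ndarray:
    """Average-referenced scalp column of a (possibly extended) source, µV."""
    return np.sum([scalp_potentials(p, q, scalp_pos, head)
                   for p, q in src.subsources(head.center)],
                  axis=0) * V_TO_UV


def _one_over_f_noise(rng, n, exponent, fs) -> np.ndarray:
    """Gaussian noise with |X(f)| ~ f^(-exponent/2) power shaping, unit RMS."""
    white = rng.normal(size=n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    return x / x.std()


def _band_noise(rng, n, fs, lo, hi) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.normal(size=n))
    return x / x.std()


def _trigger_wave(times, trig_times, width) -> np.ndarray:
    x = np.zeros_like(times)
    for t0 in trig_times:
        x[(times >= t0) & (times < t0 + width)] = 100.0
    return x


def simulate_session(config: SimulationConfig, sensors: SensorArray,
                     head: HeadModel, sources):
    """Render one simultaneous session.

    Returns (scalp Recording, seeg Recording, GroundTruth). The first
    source in `sources` is taken as the ictal generator of record; its
    SOZ is the two depth contacts nearest the source.
    """
    from scipy.interpolate import CubicSpline

    sensors.validate(head)
    sources = list(sources)
    if not sources:
        raise ValueError("at least one source required")
    for s in sources:
        if head.eccentricity(s.position) >= 1.0:
            raise ValueError("source lies outside the head sphere")

    rng = np.random.default_rng(config.seed)
    fs, dur = config.fs, config.duration
    n = int(round(dur * fs)) + 1  # span [0, duration] inclusive
    delta = config.clock_drift_ppm * 1e-6
    lag_s = config.imposed_lag / fs

    # master clock grid padded so the drifting stream can be interpolated
    pad = int(np.ceil(abs(config.imposed_lag))) + int(np.ceil(
        abs(delta) * n)) + 16
    idx = np.arange(-pad, n + pad)
    t_master = idx / fs
    nm = len(idx)

    scalp_pos = sensors.scalp_positions()
    seeg_pos = sensors.seeg_positions()
    scalp_labels = sensors.scalp_labels()
    seeg_labels = sensors.seeg_labels()

    scalp_sig = np.zeros((len(scalp_labels), nm))
    seeg_sig = np.zeros((len(seeg_labels), nm))

    # ictal + any explicitly specified sources
    for k, src in enumerate(sources):
        w = synth_ictal_waveform(
            src.pattern, src.characteristic_frequency, src.onset_time + pad / fs,
            dur + 2 * pad / fs, fs, seed=int(rng.integers(2**31)),
            n_samples=nm)
        g_sc = _source_scalp_gain(src, scalp_pos, head)
        g_se = np.sum([seeg_potentials(p, q, seeg_pos, head.conductivity)
                       for p, q in src.subsources(head.center)],
                      axis=0) * V_TO_UV
        scalp_sig += np.outer(g_sc, w)
        seeg_sig += np.outer(g_se, w)

    # spatially distributed 1/f background generators
    for _ in range(config.n_background_sources):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = 0.85 * head.radius * rng.random() ** (1 / 3)
        pos = head.center + r * u
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        w = _one_over_f_noise(rng, nm, config.background_exponent, fs)
        m = config.background_amplitude * ori
        scalp_sig += np.outer(scalp_potentials(pos, m, scalp_pos, head)
                              * V_TO_UV, w)
        seeg_sig += np.outer(seeg_potentials(pos, m, seeg_pos,
                                             head.conductivity) * V_TO_UV, w)

    # pulses at j*interval for j = 0..floor(duration/interval); the first one
    # is emitted one sample late so its rising edge is recordable
    trig_times = np.arange(0, dur + 1e-9, config.trigger_interval)
    trig_times[0] += 1.0 / fs

    # ---- scalp stream: master clock, samples 0..n-1 -------------------
    sel = slice(pad, pad + n)
    t_a = t_master[sel]
    scalp_data = scalp_sig[:, sel].copy()
    # EMG draws are taken even at level 0 so the rng stream (and hence the
    # rest of the session) is invariant to the EMG setting
    for i, lab in enumerate(scalp_labels):
        if lab in TEMPORAL_LABELS:
            scalp_data[i] += config.emg_level * _band_noise(
                rng, n, fs, 20.0, min(100.0, 0.45 * fs))
    scalp_data += config.sensor_noise * rng.normal(size=scalp_data.shape)
    scalp_rows = np.vstack([
        scalp_data,
        _trigger_wave(t_a, trig_times, 0.02),
        50.0 * np.sin(2 * np.pi * config.ref_sine_freq * t_a),
    ])
    scalp_rec = icio.Recording(
        scalp_rows, scalp_labels + ["TRIG", "SINE"], fs,
        [icio.CH_SCALP] * len(scalp_labels) + [icio.CH_TRIGGER,
                                               icio.CH_REFSINE])

    # ---- seeg stream: delayed, drifting clock -------------------------
    tau = lag_s + np.arange(n) * (1 + delta) / fs  # physical sample times
    spline = CubicSpline(t_master, seeg_sig, axis=1)
    seeg_data = spline(tau)
    seeg_data += config.sensor_noise * rng.normal(size=seeg_data.shape)
    seeg_rows = np.vstack([
        seeg_data,
        _trigger_wave(tau, trig_times, 0.02),
        50.0 * np.sin(2 * np.pi * config.ref_sine_freq * tau),
    ])
    seeg_rec = icio.Recording(
        seeg_rows, seeg_labels + ["TRIG", "SINE"], fs,
        [icio.CH_SEEG] * len(seeg_labels) + [icio.CH_TRIGGER,
                                             icio.CH_REFSINE],
        start_offset=lag_s)

    ictal = sources[0]
    d = np.linalg.norm(seeg_pos - ictal.position, axis=1)
    order = np.argsort(d)
    soz = sorted([seeg_labels[order[0]], seeg_labels[order[1]]])
    gt = GroundTruth(
        source=ictal,
        scalp_mixing=_source_scalp_gain(ictal, scalp_pos, head),
        soz_labels=soz,
        imposed_lag=config.imposed_lag,
        clock_drift_ppm=config.clock_drift_ppm,
        trigger_times=trig_times,
    )
    return scalp_rec, seeg_rec, gt


def depth_scenario(eccentricity: float, seed: int = 0,
                   config: SimulationConfig | None = None,
                   pattern: str = "lvfa",
                   characteristic_frequency: float = 40.0,
                   onset_time: float | None = None,
                   amplitude: float = 75.0,
                   extent_mm: float = 18.0,
                   preictal_spike_amplitude: float | None = None):
    """Standard single-focus session at a controllable source depth.

    One radial ictal dipole at `eccentricity`·R along a right-parietal
    direction, one 16-contact depth shaft running along the same radial
    line (so contacts straddle the source at any depth), a reduced 10-20
    cap, and the default background/noise mix.

    Returns (config, sensors, head, sources).
    """
    if not 0.0 < eccentricity <= 0.9:
        raise ValueError("eccentricity must be in (0, 0.9]")
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    head = HeadModel()
    u = np.array([0.55, -0.35, 0.76])
    u /= np.linalg.norm(u)
    scalp = standard_scalp_cap(head)
    tip_depth = 24.5
    # keep every contact at least half a millimetre from the source; a
    # contact sitting exactly on the generator is unphysical (and the
    # point-dipole potential diverges there)
    k_near = round((eccentricity * head.radius - tip_depth) / 3.5)
    if abs(tip_depth + 3.5 * k_near - eccentricity * head.radius) < 0.5:
        tip_depth += 1.75
    shaft = make_shaft("V", head.center + tip_depth * u, u, n_contacts=16)
    # two remote shafts sample brain regions away from the focus, as real
    # multi-electrode implantations do; their pairs anchor the "ordinary
    # plane" end of the Ns distribution for the outlier rule
    shafts = [shaft]
    for lab, direction in [("T", [-0.70, -0.45, 0.55]),
                           ("P", [-0.20, 0.75, 0.63])]:
        v = np.asarray(direction, float)
        v /= np.linalg.norm(v)
        shafts.append(make_shaft(lab, head.center + 26.0 * v, v,
                                 n_contacts=12))
    sensors = SensorArray(scalp=scalp, shafts=shafts)
    if onset_time is None:
        onset_time = config.duration * 2.0 / 3.0  # leaves 1/3 of ictal run
    src = SourceSpec(position=head.center + eccentricity * head.radius * u,
                     orientation=u, pattern=pattern,
                     characteristic_frequency=characteristic_frequency,
                     onset_time=onset_time, amplitude=amplitude,
                     extent_mm=extent_mm)
    sources = [src]
    # the seizure-onset region also fires sporadic interictal spikes before
    # SO — typical of focal epilepsies, and the reason the analysis epoch
    # keeps 20 s of preictal data
    if preictal_spike_amplitude is None:
        preictal_spike_amplitude = 0.8 * amplitude
    if preictal_spike_amplitude > 0:
        sources.append(SourceSpec(
            position=src.position, orientation=src.orientation,
            pattern="preictal_spikes", characteristic_frequency=1.0,
            onset_time=onset_time, amplitude=preictal_spike_amplitude,
            extent_mm=extent_mm))
    return config, sensors, head, sources


def write_session(scalp_rec, seeg_rec, gt: GroundTruth, sensors: SensorArray,
                  outdir) -> dict:
    """Write a simulated session: two EDFs, a coordinates TSV, a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"scalp": outdir / "scalp.edf", "seeg": outdir / "seeg.edf",
             "coords": outdir / "sensors.tsv",
             "truth": outdir / "ground_truth.json"}
    icio.write_recording(scalp_rec, paths["scalp"])
    icio.write_recording(seeg_rec, paths["seeg"])
    icio.write_coordinates_tsv(sensors, paths["coords"])
    truth = {
        "source": {
            "position_mm": gt.source.position.tolist(),
            "orientation": gt.source.orientation.tolist(),
            "pattern": gt.source.pattern,
            "characteristic_frequency_hz": gt.source.characteristic_frequency,
            "onset_time_s": gt.source.onset_time,
            "amplitude_nam": gt.source.amplitude,
            "extent_mm": gt.source.extent_mm,
        },
        "scalp_mixing_uv": gt.scalp_mixing.tolist(),
        "soz_labels": gt.soz_labels,
        "imposed_lag_samples": gt.imposed_lag,
        "clock_drift_ppm": gt.clock_drift_ppm,
        "trigger_times_s": gt.trigger_times.tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
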