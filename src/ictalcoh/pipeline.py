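"""End-to-end orchestration: simulate/load → align → preprocess → ICA →
dipole fit → wavelet coherence → spatial report.

`run_pipeline` drives the whole analysis from a single PipelineConfig and
writes deterministic tables (fixed float formats, no timestamps) plus a
manifest carrying the config hash and all seeds, so identical configs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .align import align_streams, merge_streams
from .coherence import (CoherencePairSummary, WaveletParams,
                        calibrate_threshold, detect_outlier_pairs, morlet_tf,
                        summarize_pair, wavelet_coherence)
from .dipole import dipoles_to_json, fill_gof
from .ica import rank_candidates, run_infomax, screen_components
from .io import (CH_SCALP, CH_SEEG, Recording, read_coordinates_tsv,
                 read_recording)
from .preprocess import EpochSpec, FilterSpec, bandpass_fir, bipolar_montage, \
    extract_epoch
from .spatial import SOZDefinition, spatial_summary
from .sphere import HeadModel


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, err: Exception):
        self.record = {"stage": stage, "error": type(err).__name__,
                       "message": str(err)}
        super().__init__(f"stage {stage!r} failed: {err}")


@dataclass
class PipelineConfig:
    """Everything one run needs; see docs for the YAML schema."""

    # inputs: either file paths or a simulation block
    scalp_path: str | None = None
    seeg_path: str | None = None
    coords_path: str | None = None
    soz_path: str | None = None
    simulate: dict | None = None  # kwargs for simulate.depth_scenario

    so_marker: float | None = None  # s; simulation fills it when None
    pre: float = 20.0
    post: float = 10.0
    band: tuple = (5.0, 100.0)
    transition: float = 2.0
    filter_seeg: bool = True

    ica_seed: int = 0
    ica_max_iter: int = 200
    n_components: int | None = None
    z_threshold: float = 10.0
    dipole_restarts: int = 10

    wavelet: dict = field(default_factory=dict)  # WaveletParams kwargs
    alpha: float = 0.05
    n_surrogates: int = 200
    surrogate_seed: int = 0
    outlier_k: float = 5.0

    component: object = "auto"  # "auto" | int | "max_sna_soz"
    head_radius: float = 90.0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # where results land is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    alignment: object
    screens: list
    ranked: list
    fits: dict
    selected_component: int
    summaries: list
    thresholds: object
    outlier_rule: object
    selected_pairs: list
    spatial: object
    ground_truth: object = None
    outputs: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the full analysis described by `cfg`."""
    gt = None
    coords = {}
    soz_labels = None

    # ---- acquire -------------------------------------------------------
    try:
        if cfg.simulate is not None:
            from .simulate import depth_scenario, simulate_session

            sim_kwargs = dict(cfg.simulate)
            sim_cfg_kwargs = sim_kwargs.pop("config", None)
            if sim_cfg_kwargs:
                from .simulate import SimulationConfig

                sim_kwargs["config"] = SimulationConfig(**sim_cfg_kwargs)
            sim_cfg, sensors, head, sources = depth_scenario(**sim_kwargs)
            scalp, seeg, gt = simulate_session(sim_cfg, sensors, head, sources)
            coords = sensors.coordinates()
            soz_labels = gt.soz_labels
            if cfg.so_marker is None:
                cfg.so_marker = sources[0].onset_time
        else:
            if not (cfg.scalp_path and cfg.seeg_path):
                raise ValueError("need scalp_path and seeg_path or a "
                                 "simulate block")
            scalp = read_recording(cfg.scalp_path)
            seeg = read_recording(cfg.seeg_path)
            head = HeadModel(radius=cfg.head_radius)
            if cfg.coords_path:
                coords = read_coordinates_tsv(cfg.coords_path)
            if cfg.soz_path:
                soz_labels = [ln.strip() for ln in
                              Path(cfg.soz_path).read_text().splitlines()
                              if ln.strip()]
        if cfg.so_marker is None:
            raise ValueError("so_marker required for file inputs")
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineError("acquire", err) from err

    # ---- align ---------------------------------------------------------
    try:
        alignment = align_streams(scalp, seeg)
        merged = merge_streams(scalp, seeg, alignment)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("align", err) from err

    # ---- preprocess ----------------------------------------------------
    try:
        fspec = FilterSpec(band=cfg.band, transition=cfg.transition)
        skip = ("trigger", "refsine") if cfg.filter_seeg else \
            ("trigger", "refsine", CH_SEEG)
        filtered = bandpass_fir(merged, fspec, skip_types=skip)
        epoch = extract_epoch(filtered, EpochSpec(cfg.so_marker, cfg.pre,
                                                  cfg.post))
        scalp_ep = epoch.pick(CH_SCALP)
        seeg_bip = bipolar_montage(epoch, coords=coords if coords else None)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("preprocess", err) from err

    # ---- ICA + screening + dipoles ------------------------------------
    try:
        decomp = run_infomax(scalp_ep, n_components=cfg.n_components,
                             seed=cfg.ica_seed, max_iter=cfg.ica_max_iter)
        screens = screen_components(decomp, cfg.z_threshold)
        elec = np.array([coords[lab] for lab in decomp.labels]) if coords \
            else None
        if elec is None:
            raise ValueError("electrode coordinates required for dipole fits")
        fits = fill_gof(decomp, screens, elec, head,
                        n_restarts=cfg.dipole_restarts, seed=cfg.ica_seed)
        ranked = rank_candidates(screens)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("ica_dipole", err) from err

    # ---- coherence -----------------------------------------------------
    try:
        wp = WaveletParams(**cfg.wavelet)
        duration = cfg.pre + cfg.post
        thr = calibrate_threshold(wp, scalp_ep.fs, duration,
                                  alpha=cfg.alpha, n=cfg.n_surrogates,
                                  seed=cfg.surrogate_seed)
        pair_tf = {lab: morlet_tf(seeg_bip.channel(lab), seeg_bip.fs, wp)
                   for lab in seeg_bip.labels}

        def plane(c, lab):
            cm = wavelet_coherence(ic_tf[c], pair_tf[lab])
            return summarize_pair(cm, thr, component=c, pair=lab)

        summaries = []
        if cfg.component == "auto":
            # automatic path: full profile of every screened candidate
            candidates = ranked if ranked else [s.component for s in screens
                                                if not s.outlier_flag]
            ic_tf = {c: morlet_tf(decomp.activations[c], scalp_ep.fs, wp)
                     for c in candidates}
            summaries = [plane(c, lab) for c in candidates
                         for lab in seeg_bip.labels]
            selected = _select_component(cfg, candidates, summaries,
                                         soz_labels)
        else:
            # expert-override path (explicit id or ground-truth-guided
            # selection): every component stays on the table — the screen
            # only feeds the automatic suggestion — but only the planes
            # needed for selection are computed before the full profile
            # of the chosen component
            candidates = list(range(decomp.n_components))
            ic_tf = {c: morlet_tf(decomp.activations[c], scalp_ep.fs, wp)
                     for c in candidates}
            if cfg.component == "max_sna_soz":
                if not soz_labels:
                    raise ValueError("max_sna_soz selection requires SOZ "
                                     "labels")
                soz_pairs = [f"{a}-{b}" for a, b in
                             zip(soz_labels[:-1], soz_labels[1:])
                             if f"{a}-{b}" in seeg_bip.labels]
                summaries = [plane(c, lab) for c in candidates
                             for lab in soz_pairs]
            selected = _select_component(cfg, candidates, summaries,
                                         soz_labels)
            done = {(s.component, s.pair) for s in summaries}
            summaries += [plane(selected, lab) for lab in seeg_bip.labels
                          if (selected, lab) not in done]
        if selected not in fits:
            from .dipole import fit_ecd

            fits[selected] = fit_ecd(decomp.mixing[:, selected], elec, head,
                                     n_restarts=cfg.dipole_restarts,
                                     seed=cfg.ica_seed + selected)
        sel_summaries = [s for s in summaries if s.component == selected]
        rule, sel_pairs = detect_outlier_pairs(sel_summaries, cfg.outlier_k)
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineError("coherence", err) from err

    # ---- spatial -------------------------------------------------------
    try:
        mids = seeg_bip.meta.get("pair_midpoints", {})
        soz = SOZDefinition.from_contacts(soz_labels, coords) \
            if soz_labels else None
        pair_sna = {s.pair: s.sna for s in sel_summaries}
        spat = spatial_summary(fits[selected].position, mids, pair_sna, soz) \
            if selected in fits and mids else None
    except Exception as err:  # noqa: BLE001
        raise PipelineError("spatial", err) from err

    bundle = ReportBundle(alignment, screens, ranked, fits, selected,
                          summaries, thr, rule, sel_pairs, spat, gt)
    if cfg.outdir:
        try:
            bundle.outputs = write_report(bundle, cfg)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("report", err) from err
    return bundle


def _select_component(cfg, candidates, summaries, soz_labels):
    if not candidates:
        raise ValueError("no candidate components to select from")
    if isinstance(cfg.component, int):
        if cfg.component not in candidates:
            warnings.warn(f"component {cfg.component} was screened out; "
                          "using it anyway per explicit override")
        return cfg.component
    if cfg.component == "max_sna_soz":
        if not soz_labels:
            raise ValueError("max_sna_soz selection requires SOZ labels")
        soz_pairs = {f"{a}-{b}" for a, b in
                     zip(soz_labels[:-1], soz_labels[1:])}
        scored = [(s.sna, s.component) for s in summaries
                  if s.pair in soz_pairs]
        if not scored:
            raise ValueError("no coherence plane matches a SOZ bipolar pair")
        return max(scored)[1]
    return candidates[0]  # "auto": best GOF


def write_report(bundle: ReportBundle, cfg: PipelineConfig) -> dict:
    """Write the deterministic report tables under cfg.outdir."""
    import pandas as pd

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()
    out = {}

    def path(name):
        out[name] = str(outdir / name)
        return outdir / name

    def write_tsv(df, name):
        # every table carries the config hash as a leading comment line
        with open(path(name), "w") as fh:
            fh.write(f"# config_hash={digest}\n")
            df.to_csv(fh, sep="\t", index=False)

    al = bundle.alignment
    path("alignment.json").write_text(json.dumps({
        "config_hash": digest, "coarse_lag_samples": al.coarse_lag,
        "fine_lag_samples": round(al.fine_lag, 6),
        "drift_ppm": round(al.drift_ppm, 6),
        "residual_samples": round(al.residual, 6),
        "fine_available": al.fine_available}, indent=1))

    rows = [(s.component, round(s.max_z, 4), s.outlier_flag,
             round(s.gof, 4) if np.isfinite(s.gof) else "",
             round(s.variance, 6), s.retained) for s in bundle.screens]
    write_tsv(pd.DataFrame(rows, columns=["component", "max_z", "flagged",
                                          "gof", "variance", "retained"]),
              "components.tsv")

    dipoles_to_json(bundle.fits, path("dipoles.json"))

    sel = {(s.component, s.pair) for s in bundle.selected_pairs}
    rows = [(s.component, s.pair, s.ns, s.total, round(s.sna, 6),
             (s.component, s.pair) in sel) for s in bundle.summaries]
    write_tsv(pd.DataFrame(rows, columns=["component", "pair", "Ns",
                                          "total", "SNA", "selected"]),
              "sna.tsv")

    thr = bundle.thresholds
    write_tsv(pd.DataFrame({"freq_hz": np.round(thr.freqs, 4),
                            "threshold": np.round(thr.threshold, 6)}),
              "thresholds.tsv")

    spat = bundle.spatial
    spat_json = None
    if spat is not None:
        spat_json = {
            "d_soz_mm": None if np.isnan(spat.d_soz_mm)
            else round(spat.d_soz_mm, 3),
            "max_coherence_pair": spat.max_coh_pair,
            "max_coherence_pair_distance_mm":
                round(spat.max_coh_distance_mm, 3),
            "pearson_r": round(spat.pearson_r, 4),
            "pearson_p": round(spat.pearson_p, 6),
            "spearman_rho": round(spat.spearman_rho, 4),
            "spearman_p": round(spat.spearman_p, 6),
        }
    path("spatial.json").write_text(json.dumps(
        {"config_hash": digest, "selected_component":
         bundle.selected_component, "summary": spat_json,
         "outlier_threshold": bundle.outlier_rule.threshold}, indent=1))

    if spat is not None:
        write_tsv(pd.DataFrame({"pair": spat.pair_labels,
                                "distance_mm": np.round(spat.distances_mm, 3),
                                "SNA": np.round(spat.sna, 6)}),
                  "profile.tsv")

    import scipy

    path("manifest.json").write_text(json.dumps({
        "config": asdict(cfg), "config_hash": digest,
        "versions": {"ictalcoh": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__},
        "seeds": {"ica": cfg.ica_seed, "surrogate": cfg.surrogate_seed},
    }, indent=1, sort_keys=True, default=str))
    return out


@dataclass
class DepthSessionResult:
    """One synthetic session analysed against its own ground truth."""

    eccentricity: float
    seed: int
    selected_component: int
    sna_soz: float  # SNA between selected IC and the true SOZ bipolar pair
    pair_sna: dict  # SNA of the selected IC against every bipolar pair
    max_pair: str
    max_pair_sna: float
    max_pair_distance_mm: float
    d_soz_mm: float
    dipole_gof: float


def analyze_depth_session(eccentricity: float, seed: int,
                          thresholds=None, fs: float = 256.0,
                          duration: float = 36.0, n_components: int = 6,
                          n_surrogates: int = 200,
                          dipole_restarts: int = 6) -> DepthSessionResult:
    """Simulate one depth-controlled session and quantify scalp visibility.

    Runs the full chain (simulate → align/merge → filter → epoch → ICA),
    selects the component with maximal SNA against the ground-truth SOZ
    bipolar pair (the test-time stand-in for the expert's choice), fits
    its dipole and measures the coherence/distance profile. A
    pre-computed SurrogateThreshold can be shared across sessions with
    matching parameters.
    """
    from .simulate import SimulationConfig, depth_scenario, simulate_session
    from .sphere import HeadModel

    sim_cfg, sensors, head, sources = depth_scenario(
        eccentricity, seed, config=SimulationConfig(fs=fs, duration=duration,
                                                    seed=seed))
    scalp, seeg, gt = simulate_session(sim_cfg, sensors, head, sources)
    alignment = align_streams(scalp, seeg)
    merged = merge_streams(scalp, seeg, alignment)
    filtered = bandpass_fir(merged, FilterSpec())
    epoch = extract_epoch(filtered, EpochSpec(sources[0].onset_time))
    coords = sensors.coordinates()
    scalp_ep = epoch.pick(CH_SCALP)
    seeg_bip = bipolar_montage(epoch, coords=coords)

    decomp = run_infomax(scalp_ep, n_components=n_components, seed=seed,
                         max_iter=80)
    wp = WaveletParams()
    if thresholds is None:
        thresholds = calibrate_threshold(wp, scalp_ep.fs,
                                         scalp_ep.n_samples / scalp_ep.fs,
                                         n=n_surrogates, seed=0)
    soz_pair = gt.soz_bipolar_label()
    soz_tf = morlet_tf(seeg_bip.channel(soz_pair), seeg_bip.fs, wp)
    sna_by_ic = {}
    ic_tf = {}
    for c in range(decomp.n_components):
        ic_tf[c] = morlet_tf(decomp.activations[c], scalp_ep.fs, wp)
        s = summarize_pair(wavelet_coherence(ic_tf[c], soz_tf), thresholds,
                           component=c, pair=soz_pair)
        sna_by_ic[c] = s.sna
    selected = max(sna_by_ic, key=sna_by_ic.get)

    pair_sna = {}
    for lab in seeg_bip.labels:
        tf = soz_tf if lab == soz_pair else morlet_tf(seeg_bip.channel(lab),
                                                      seeg_bip.fs, wp)
        s = summarize_pair(wavelet_coherence(ic_tf[selected], tf), thresholds,
                           component=selected, pair=lab)
        pair_sna[lab] = s.sna

    from .dipole import fit_ecd

    elec = np.array([coords[lab] for lab in decomp.labels])
    fit = fit_ecd(decomp.mixing[:, selected], elec, head,
                  n_restarts=dipole_restarts, seed=seed)
    mids = seeg_bip.meta["pair_midpoints"]
    soz = SOZDefinition.from_contacts(gt.soz_labels, coords)
    max_pair = max(pair_sna, key=pair_sna.get)
    return DepthSessionResult(
        eccentricity=eccentricity, seed=seed, selected_component=selected,
        sna_soz=pair_sna[soz_pair], pair_sna=pair_sna, max_pair=max_pair,
        max_pair_sna=pair_sna[max_pair],
        max_pair_distance_mm=float(np.linalg.norm(fit.position
                                                  - mids[max_pair])),
        d_soz_mm=float(np.linalg.norm(fit.position - soz.center)),
        dipole_gof=fit.gof)


def depth_sweep(eccentricities=(0.45, 0.55, 0.65, 0.75, 0.85),
                seeds=(0, 1, 2, 3, 4), **kwargs) -> list:
    """Depth-visibility experiment: sessions at several source depths.

    Shares one surrogate calibration across sessions. Returns a list of
    DepthSessionResult, one per (eccentricity, seed).
    """
    fs = kwargs.get("fs", 256.0)
    duration = kwargs.get("duration", 36.0)
    wp = WaveletParams()
    thr = calibrate_threshold(wp, fs, 30.0,
                              n=kwargs.pop("n_surrogates", 200), seed=0)
    out = []
    for ecc in eccentricities:
        for seed in seeds:
            out.append(analyze_depth_session(ecc, seed, thresholds=thr,
                                             **kwargs))
    return out


def save_planes_h5(path, ic_tf: dict, coherence_maps: dict) -> None:
    """Persist TF/coherence planes to HDF5 for later inspection."""
    import h5py

    with h5py.File(path, "w") as h5:
        g = h5.create_group("component_tf")
        for c, tf in ic_tf.items():
            gg = g.create_group(str(c))
            gg.create_dataset("coefficients", data=tf.coefficients)
            gg.create_dataset("freqs", data=tf.freqs)
        g = h5.create_group("coherence")
        for key, cm in coherence_maps.items():
            gg = g.create_group(str(key))
            gg.create_dataset("coherence", data=cm.coherence)
            gg.create_dataset("edge_mask", data=cm.edge_mask)
            gg.create_dataset("freqs", data=cm.freqs)
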