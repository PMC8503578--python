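"""Extended-infomax ICA of scalp epochs and automatic component screening.

The ictal generator, if visible on scalp at all, should appear as one
independent component whose topography is dipolar. Screening removes
components dominated by a single electrode (loose contact / artifact) and
keeps only components whose equivalent-dipole goodness of fit exceeds
90%, the convention for "putative brain source".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CH_SCALP, Recording


@dataclass
class ICADecomposition:
    """Unmixing/mixing pair with unit-variance component activations."""

    unmixing: np.ndarray  # components × channels
    mixing: np.ndarray  # channels × components
    activations: np.ndarray  # components × samples
    labels: list
    fs: float
    data_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def topographies(self) -> np.ndarray:
        """Columns of the mixing matrix: scalp pattern of each component."""
        return self.mixing

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.activations + self.data_mean[:, None]


@dataclass
class ComponentScreen:
    component: int
    outlier_flag: bool
    max_z: float
    gof: float = np.nan
    variance: float = 0.0

    @property
    def retained(self) -> bool:
        return (not self.outlier_flag) and self.gof > 90.0


def run_infomax(rec: Recording, n_components: int | None = None,
                seed: int = 0, w_change: float = 1e-7,
                max_iter: int = 200) -> ICADecomposition:
    """Extended-infomax ICA on the scalp channels of a filtered epoch.

    Data are PCA-whitened (dimension reduced to the numerical rank, with
    a warning, if rank-deficient) before the extended-infomax rotation.
    Activations are scaled to unit variance, pushing all amplitude into
    the mixing columns; mixing @ activations + mean reproduces the input.
    """
    from mne.preprocessing import infomax

    scalp = rec.pick(CH_SCALP) if CH_SCALP in rec.channel_types else rec
    x = scalp.data
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    n_ch, n_samp = xc.shape
    if n_samp < 4 * n_ch**2:
        warnings.warn("few samples relative to channels^2; ICA may be "
                      "unstable")

    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    k = min(n_components or rank, rank)
    if n_components is not None and k < n_components:
        warnings.warn(f"rank-deficient data: reducing to {k} components")
    whitener = (u[:, :k] / s[:k]).T * np.sqrt(n_samp)  # k × channels
    z = whitener @ xc  # unit-variance, decorrelated

    w = infomax(z.T, extended=True, random_state=seed, w_change=w_change,
                max_iter=max_iter, verbose="error")
    unmixing = w @ whitener
    acts = unmixing @ xc
    sd = acts.std(axis=1)
    sd[sd == 0] = 1.0
    unmixing = unmixing / sd[:, None]
    acts = acts / sd[:, None]
    mixing = np.linalg.pinv(unmixing)
    return ICADecomposition(unmixing, mixing, acts, list(scalp.labels),
                            scalp.fs, mean)


def screen_outlier_topography(topography, threshold: float = 10.0):
    """Leave-one-out Z of each electrode's |weight| in a component map.

    For electrode i, Z_i = |v_i - mean(v_others)| / SD(v_others) on the
    absolute topography values. The naive all-in Z is bounded by
    (n-1)/sqrt(n) and could never exceed 10 on a 20-37 electrode cap, so
    the exclusion criterion is read as leave-one-out.

    Returns (flag, max_z).
    """
    v = np.abs(np.asarray(topography, float))
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 electrodes")
    scale = v.max() if v.max() > 0 else 1.0
    tiny = 1e-12 * scale
    max_z = 0.0
    for i in range(n):
        rest = np.delete(v, i)
        sd = rest.std(ddof=1)
        dev = abs(v[i] - rest.mean())
        if dev <= tiny:  # numerically indistinguishable from the rest
            z = 0.0
        elif sd <= tiny:
            z = np.inf
        else:
            z = dev / sd
        max_z = max(max_z, z)
    return bool(max_z > threshold), float(max_z)


def screen_components(decomp: ICADecomposition,
                      z_threshold: float = 10.0) -> list:
    """Run the outlier-electrode screen on every component topography."""
    out = []
    var = (decomp.mixing**2).sum(axis=0)  # component variance in data units
    for c in range(decomp.n_components):
        flag, mz = screen_outlier_topography(decomp.mixing[:, c], z_threshold)
        out.append(ComponentScreen(c, flag, mz, variance=float(var[c])))
    return out


def save_decomposition_h5(decomp: ICADecomposition, path,
                          screens=None) -> None:
    """Persist unmixing/mixing/activations (and screening) to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("unmixing", data=decomp.unmixing)
        h5.create_dataset("mixing", data=decomp.mixing)
        h5.create_dataset("activations", data=decomp.activations)
        h5.create_dataset("data_mean", data=decomp.data_mean)
        h5.attrs["fs"] = decomp.fs
        h5.attrs["labels"] = [str(lab) for lab in decomp.labels]
        if screens is not None:
            g = h5.create_group("screen")
            g.create_dataset("component",
                             data=[s.component for s in screens])
            g.create_dataset("outlier_flag",
                             data=[s.outlier_flag for s in screens])
            g.create_dataset("max_z", data=[s.max_z for s in screens])
            g.create_dataset("gof", data=[s.gof for s in screens])
            g.create_dataset("variance", data=[s.variance for s in screens])


def load_decomposition_h5(path):
    """Inverse of save_decomposition_h5; returns (decomp, screens|None)."""
    import h5py

    with h5py.File(path, "r") as h5:
        decomp = ICADecomposition(
            h5["unmixing"][()], h5["mixing"][()], h5["activations"][()],
            [str(lab) for lab in h5.attrs["labels"]], float(h5.attrs["fs"]),
            h5["data_mean"][()])
        screens = None
        if "screen" in h5:
            g = h5["screen"]
            screens = [ComponentScreen(int(c), bool(f), float(z),
                                       gof=float(gof), variance=float(v))
                       for c, f, z, gof, v in zip(
                           g["component"][()], g["outlier_flag"][()],
                           g["max_z"][()], g["gof"][()], g["variance"][()])]
    return decomp, screens


def plot_topographies(decomp: ICADecomposition, positions, path) -> None:
    """Render 2-D top-view component maps to a PNG (display helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.asarray(positions, float)
    k = decomp.n_components
    ncol = min(k, 5)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    for c in range(k):
        ax = axes[c // ncol][c % ncol]
        v = decomp.mixing[:, c]
        sc = ax.scatter(pos[:, 0], pos[:, 1], c=v, cmap="RdBu_r",
                        vmin=-np.abs(v).max(), vmax=np.abs(v).max(), s=60)
        ax.set_title(f"IC{c}", fontsize=8)
        ax.set_aspect("equal")
        ax.axis("off")
    for j in range(k, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.colorbar(sc, ax=axes, shrink=0.6)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rank_candidates(screens) -> list:
    """Candidate ictal components: unflagged, GOF > 90%, best GOF first.

    Ties in GOF break by component variance (descending). Returns the
    ordered component ids; empty (with a warning) when nothing survives.
    """
    kept = [s for s in screens if s.retained]
    if not kept:
        warnings.warn("no components retained after screening")
        return []
    kept.sort(key=lambda s: (-s.gof, -s.variance))
    return [s.component for s in kept]
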