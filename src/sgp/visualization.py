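"""Pseudo-colored GP maps, plots, and 3D GP volume assembly.

GP maps are rendered with a lookup table linearly scaled over the fixed
GP range [-1, 1] so colors are comparable across images and instruments;
invalid pixels are drawn in a reserved background color that never occurs
in the LUT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import tifffile
from matplotlib import cm

from .gp import GPMap
from .stats import GaussianFit, ObjectRecord, SpectrumProfile, _gauss1

#: reserved RGB for invalid pixels (dark gray, not part of any LUT)
BACKGROUND_RGB = (30, 30, 30)
DEFAULT_LUT = "jet"  # blue -> green -> red perceptual ramp, 256 entries


@dataclass
class GPVolume:
    """A z-stack of GP maps with physical voxel spacing."""

    gp: np.ndarray  # (z, y, x)
    valid: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (z, y, x)

    def __post_init__(self) -> None:
        if self.gp.shape != self.valid.shape or self.gp.ndim != 3:
            raise ValueError("gp and valid must be matching 3-D arrays")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel spacings must be positive")


def lut_index(gp: np.ndarray | float, n_entries: int = 256) -> np.ndarray:
    """Linear LUT index: gp=-1 -> 0, gp=+1 -> n_entries-1 (monotone)."""
    x = (np.asarray(gp, dtype=float) + 1.0) / 2.0
    return np.clip(np.round(x * (n_entries - 1)), 0, n_entries - 1).astype(int)


def _lut_colors(name: str, n_entries: int = 256) -> np.ndarray:
    cmap = plt.get_cmap(name, n_entries)
    return (cmap(np.arange(n_entries))[:, :3] * 255).astype(np.uint8)


def render_gp_map(
    gpmap: GPMap, lut: str = DEFAULT_LUT, n_entries: int = 256
) -> np.ndarray:
    """RGB uint8 image of a GP map under the fixed [-1, 1] LUT scaling."""
    colors = _lut_colors(lut, n_entries)
    idx = lut_index(np.nan_to_num(gpmap.gp, nan=0.0), n_entries)
    rgb = colors[idx]
    rgb[~gpmap.valid] = BACKGROUND_RGB
    return rgb


def save_gp_map_figure(
    gpmap: GPMap, path: str | Path, lut: str = DEFAULT_LUT, title: str | None = None
) -> Path:
    """GP map figure with a color bar annotated -1..1."""
    rgb = render_gp_map(gpmap, lut)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(rgb)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    sm = cm.ScalarMappable(
        cmap=plt.get_cmap(lut), norm=matplotlib.colors.Normalize(-1, 1)
    )
    fig.colorbar(sm, ax=ax, label="GP", ticks=[-1, -0.5, 0, 0.5, 1])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def build_gp_volume(
    slices: list[GPMap], z_step_um: float, pixel_size_um: float
) -> GPVolume:
    """Stack per-slice GP maps into a physical 3-D volume (lossless)."""
    if not slices:
        raise ValueError("need at least one slice")
    shapes = {s.gp.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slice shapes differ: {sorted(shapes)}")
    gp = np.stack([s.gp for s in slices], axis=0)
    valid = np.stack([s.valid for s in slices], axis=0)
    return GPVolume(
        gp=gp, valid=valid, voxel_size_um=(z_step_um, pixel_size_um, pixel_size_um)
    )


def export_volume_pointset(
    volume: GPVolume, path: str | Path, lut: str = DEFAULT_LUT
) -> Path:
    """CSV point set (x_um, y_um, z_um, gp, r, g, b) of valid voxels."""
    colors = _lut_colors(lut)
    zs, ys, xs = np.nonzero(volume.valid)
    gp = volume.gp[zs, ys, xs]
    rgb = colors[lut_index(gp)]
    dz, dy, dx = volume.voxel_size_um
    header = "x_um,y_um,z_um,gp,r,g,b"
    data = np.column_stack([xs * dx, ys * dy, zs * dz, gp, rgb])
    np.savetxt(
        path,
        data,
        delimiter=",",
        header=header,
        comments="",
        fmt=["%.6g"] * 4 + ["%d"] * 3,
    )
    return Path(path)


def export_volume_tiff(
    volume: GPVolume, path: str | Path, lut: str = DEFAULT_LUT
) -> Path:
    """Multi-page TIFF of rendered (RGB) volume slices."""
    colors = _lut_colors(lut)
    pages = []
    for z in range(volume.gp.shape[0]):
        idx = lut_index(np.nan_to_num(volume.gp[z], nan=0.0))
        rgb = colors[idx]
        rgb[~volume.valid[z]] = BACKGROUND_RGB
        pages.append(rgb)
    tifffile.imwrite(str(path), np.stack(pages), photometric="rgb")
    return Path(path)


def plot_spectrum(
    spectrum: SpectrumProfile, path: str | Path, title: str | None = None
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(spectrum.wavelengths, spectrum.mean_intensity, "o-")
    ax.set_xlim(spectrum.wavelengths[0], spectrum.wavelengths[-1])
    ax.set_xlabel("Emission wavelength (nm)")
    ax.set_ylabel("Mean intensity")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_gp_histogram(
    centers: np.ndarray,
    counts: np.ndarray,
    fit: GaussianFit | None,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """GP histogram with the fitted Gaussian model(s) overlaid.

    For a two-peak fit both components and their sum are drawn.
    """
    fig, ax = plt.subplots(figsize=(5, 3.5))
    width = centers[1] - centers[0] if len(centers) > 1 else 0.01
    ax.bar(centers, counts, width=width, color="0.7", label="GP histogram")
    if fit is not None and fit.n_peaks >= 1:
        x = np.linspace(-1, 1, 400)
        total = np.zeros_like(x)
        for a, mu, s in zip(fit.amplitudes, fit.means, fit.sigmas):
            comp = _gauss1(x, a, mu, s)
            total += comp
            if fit.n_peaks == 2:
                ax.plot(x, comp, "--", lw=1)
        label = f"{fit.n_peaks}-peak fit (RMSE {fit.selected_rmse:.3g})"
        ax.plot(x, total, "r-", lw=1.5, label=label)
    ax.set_xlim(-1, 1)
    ax.set_xlabel("GP")
    ax.set_ylabel("Pixel count")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_outputs(
    record: ObjectRecord,
    out_dir: str | Path,
    gpmap: GPMap | None = None,
    object_mask: np.ndarray | None = None,
    spectrum: SpectrumProfile | None = None,
    histogram: tuple[np.ndarray, np.ndarray] | None = None,
    lut: str = DEFAULT_LUT,
) -> list[Path]:
    """Write the per-object figure set with deterministic names.

    Files are prefixed ``{source_id}_obj{object_id}_`` with kinds
    ``gpmap``, ``spectrum``, ``histogram``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = f"{record.source_id}_obj{record.object_id}_"
    written: list[Path] = []
    if gpmap is not None:
        gm = gpmap
        if object_mask is not None:
            gm = GPMap(
                gp=gpmap.gp,
                valid=gpmap.valid & object_mask.astype(bool),
                channel_pair=gpmap.channel_pair,
                g_factor=gpmap.g_factor,
            )
        written.append(
            save_gp_map_figure(gm, out_dir / f"{prefix}gpmap.png", lut=lut)
        )
    if spectrum is not None:
        written.append(plot_spectrum(spectrum, out_dir / f"{prefix}spectrum.png"))
    if histogram is not None:
        centers, counts = histogram
        written.append(
            plot_gp_histogram(
                centers, counts, record.gp_fit, out_dir / f"{prefix}histogram.png"
            )
        )
    return written
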