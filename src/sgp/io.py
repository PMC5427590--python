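"""Reading and writing spectral (lambda) image stacks and pipeline outputs.

A lambda stack is an image series in which each plane records a distinct
emission-wavelength band, so the per-pixel sequence along the channel axis
is an emission spectrum.  Stacks may additionally carry z (depth) and t
(time) dimensions ("hyperstacks").  Supported on-disk formats are plain
TIFF and OME-TIFF; per-channel band centers are taken from the OME
``EmissionWavelength`` channel attributes when present, otherwise they must
be supplied by the caller.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: canonical in-memory axis order
CANONICAL_AXES = "YXCZT"

#: fixed column order of the summary spreadsheet
SUMMARY_COLUMNS = [
    "source_id",
    "object_id",
    "area_px",
    "area_um2",
    "mean_gp",
    "membrane_mean_gp",
    "radius_px",
    "diameter_um",
    "fit_n_peaks",
    "fit_mean_1",
    "fit_mean_2",
    "fit_sigma_1",
    "fit_sigma_2",
    "fit_amplitude_1",
    "fit_amplitude_2",
    "fit_rmse_1",
    "fit_rmse_2",
]


class StackFormatError(ValueError):
    """Raised when a file cannot be interpreted as a spectral stack."""


@dataclass
class SpectralStack:
    """A multi-wavelength intensity stack with physical calibration.

    Parameters
    ----------
    intensities
        Non-negative array with canonical axes ``(y, x, c, z, t)``; the z
        and t axes are always present (length 1 for plain 2-D stacks).
    wavelengths
        Per-channel emission band centers in nm, strictly increasing.
    pixel_size_um
        Lateral physical pixel size (x and y assumed equal), in microns.
    z_step_um
        Slice spacing in microns; required when the stack has z depth > 1.
    source_id
        Provenance string, typically the file stem.
    """

    intensities: np.ndarray
    wavelengths: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float | None = None
    source_id: str = "stack"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim == 3:  # (y, x, c)
            self.intensities = self.intensities[:, :, :, None, None]
        elif self.intensities.ndim == 4:  # (y, x, c, z)
            self.intensities = self.intensities[:, :, :, :, None]
        if self.intensities.ndim != 5:
            raise StackFormatError(
                f"intensities must have 3-5 dims (y,x,c[,z,t]); got {self.intensities.ndim}"
            )
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.n_channels:
            raise StackFormatError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"channel dimension {self.n_channels}"
            )
        if self.n_channels < 2:
            raise StackFormatError("a spectral stack needs at least 2 channels")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise StackFormatError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise StackFormatError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise StackFormatError("pixel_size_um must be positive")
        if self.n_z > 1 and (self.z_step_um is None or not self.z_step_um > 0):
            raise StackFormatError("z_step_um must be positive for a z-stack")

    # -- geometry ---------------------------------------------------------
    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.intensities.shape[0], self.intensities.shape[1]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    @property
    def n_z(self) -> int:
        return self.intensities.shape[3]

    @property
    def n_t(self) -> int:
        return self.intensities.shape[4]

    def plane(self, z: int = 0, t: int = 0) -> np.ndarray:
        """Return the ``(y, x, c)`` spectral image at one (z, t) position."""
        return self.intensities[:, :, :, z, t]

    def summed_intensity(self, z: int = 0, t: int = 0) -> np.ndarray:
        """Total intensity over all channels — the detection image."""
        return self.plane(z, t).sum(axis=2)


def _parse_ome_wavelengths(ome_xml: str) -> list[float] | None:
    """Extract per-channel EmissionWavelength values from OME-XML."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    tag = "ome:Channel" if ns else "Channel"
    out: list[float] = []
    for ch in root.iter():
        if ch.tag.endswith("Channel"):
            ew = ch.get("EmissionWavelength")
            if ew is None:
                return None
            out.append(float(ew))
    return out or None


def _parse_ome_physical(ome_xml: str) -> tuple[float | None, float | None]:
    """Return (pixel_size_um, z_step_um) from OME Pixels attributes."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            px = el.get("PhysicalSizeX")
            pz = el.get("PhysicalSizeZ")
            return (
                float(px) if px is not None else None,
                float(pz) if pz is not None else None,
            )
    return None, None


def _to_canonical(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to canonical (y, x, c, z, t).

    ``axes`` is the tifffile axes string (e.g. ``'ZCYX'``, ``'TCYX'``);
    missing axes are inserted with length 1.  The sample axis ``'S'`` is
    rejected — RGB TIFFs are not spectral stacks.
    """
    axes = axes.upper()
    if "S" in axes:
        # sample-interleaved storage: accept samples as channels only when
        # no channel axis exists
        if "C" in axes:
            raise StackFormatError("TIFF with both channel and sample axes")
        axes = axes.replace("S", "C")
    unknown = set(axes) - set("YXCZTQI")
    if unknown:
        raise StackFormatError(f"unsupported axes {unknown!r} in TIFF")
    # tifffile uses Q/I for unknown axes on bare multi-page TIFFs; a bare
    # page sequence is interpreted as the channel axis.
    axes = axes.replace("Q", "C").replace("I", "C")
    if "C" not in axes and data.ndim == 2:
        raise StackFormatError("single-plane TIFF has no channel axis")
    for ax in CANONICAL_AXES:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in CANONICAL_AXES]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    wavelengths: Sequence[float] | None = None,
    wavelength_start_step: tuple[float, float] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> SpectralStack:
    """Read a TIFF/OME-TIFF lambda stack into canonical layout.

    Wavelength resolution order: explicit ``wavelengths`` override, then a
    uniform grid from ``wavelength_start_step=(start_nm, step_nm)``, then
    OME ``EmissionWavelength`` metadata.  Physical sizes follow the same
    override-then-metadata rule; a missing pixel size falls back to 1.0 µm
    with a warning so that size outputs are still produced in pixel units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tf.ome_metadata
    except (tifffile.TiffFileError, IndexError) as exc:
        raise StackFormatError(f"unreadable TIFF file {path}: {exc}") from exc

    data = _to_canonical(np.asarray(data), axes)
    n_c = data.shape[2]
    if n_c < 2:
        raise StackFormatError(f"{path}: channel count {n_c} < 2")

    wl: np.ndarray | None = None
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size != n_c:
            raise StackFormatError(
                f"wavelength override length {wl.size} != channel count {n_c}"
            )
    elif wavelength_start_step is not None:
        start, step = wavelength_start_step
        wl = start + step * np.arange(n_c)
    elif ome_xml:
        parsed = _parse_ome_wavelengths(ome_xml)
        if parsed is not None:
            if len(parsed) != n_c:
                raise StackFormatError(
                    f"OME metadata lists {len(parsed)} wavelengths for {n_c} channels"
                )
            wl = np.asarray(parsed, dtype=float)
    if wl is None:
        raise StackFormatError(
            f"{path}: missing wavelengths — no OME EmissionWavelength metadata "
            "and no override supplied"
        )

    meta_px, meta_z = (None, None)
    if ome_xml:
        meta_px, meta_z = _parse_ome_physical(ome_xml)
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        warnings.warn(
            f"{path.name}: no pixel size available; defaulting to 1.0 µm "
            "(size outputs are in pixel units)",
            stacklevel=2,
        )
        px = 1.0
    zs = z_step_um if z_step_um is not None else meta_z
    if data.shape[3] > 1 and zs is None:
        warnings.warn(
            f"{path.name}: z-stack without z spacing; defaulting to 1.0 µm",
            stacklevel=2,
        )
        zs = 1.0

    return SpectralStack(
        intensities=data.astype(np.float64),
        wavelengths=wl,
        pixel_size_um=float(px),
        z_step_um=zs,
        source_id=path.stem.replace(".ome", ""),
    )


def write_stack(stack: SpectralStack, path: str | Path) -> Path:
    """Write a stack to OME-TIFF with full wavelength/physical metadata."""
    path = Path(path)
    # OME planar order TZCYX
    data = np.transpose(stack.intensities, (4, 3, 2, 0, 1)).astype(np.float32)
    n_c = stack.n_channels
    metadata = {
        "axes": "TZCYX",
        "Channel": {
            "EmissionWavelength": [float(w) for w in stack.wavelengths],
            "EmissionWavelengthUnit": ["nm"] * n_c,
        },
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(str(path), data, ome=True, metadata=metadata)
    return path


def records_to_table(records: Sequence["object"]) -> pd.DataFrame:
    """Assemble ObjectRecord-like rows into the summary DataFrame.

    Each record must expose ``to_row()`` returning a dict keyed by the
    entries of :data:`SUMMARY_COLUMNS`.  Keys are (source_id, object_id);
    duplicates are rejected.
    """
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(df) and df.duplicated(subset=["source_id", "object_id"]).any():
        raise ValueError("duplicate (source_id, object_id) keys in summary")
    return df


def write_summary(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the summary spreadsheet as CSV with the fixed column order."""
    path = Path(path)
    out = table.reindex(columns=SUMMARY_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
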