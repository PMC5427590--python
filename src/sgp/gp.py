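"""Per-pixel generalized polarization (GP).

GP quantifies the emission spectral shift of a polarity-sensitive membrane
probe (Laurdan, C-Laurdan, Di-4-ANEPPDHQ, FE):

    GP = (I_B - I_R) / (I_B + I_R)

where I_B and I_R are intensities at a blue and red emission wavelength
chosen at the probe's emission maxima in liquid-ordered and
liquid-disordered reference phases.  GP ranges from -1 (fully disordered)
to +1 (fully ordered).  Because GP is intensity-ratio based, channel gains
must be calibrated to report absolute values; a reference solution of known
fluorimeter GP yields a multiplicative correction factor

    G = (I_B,ref * (1 - GP_ref)) / (I_R,ref * (1 + GP_ref))

applied as GP = (I_B - G*I_R) / (I_B + G*I_R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import SpectralStack


@dataclass(frozen=True)
class ChannelPair:
    """The two stack channels used for the GP ratio."""

    lambda_b_nm: float
    lambda_r_nm: float
    index_b: int
    index_r: int
    actual_b_nm: float
    actual_r_nm: float

    def __post_init__(self) -> None:
        if self.index_b == self.index_r:
            raise ValueError("blue and red wavelengths select the same channel")
        if not self.actual_b_nm < self.actual_r_nm:
            raise ValueError("blue channel must be bluer than the red channel")


@dataclass(frozen=True)
class CorrectionFactor:
    """Channel-gain calibration from a reference of known GP."""

    g: float
    gp_ref: float
    i_b_ref: float
    i_r_ref: float


@dataclass
class GPMap:
    """Per-pixel GP with a validity mask.

    Invalid pixels are exactly those failing the significant-signal
    criterion or having a non-positive denominator; they carry NaN and are
    excluded from all downstream histograms, spectra and means.
    """

    gp: np.ndarray
    valid: np.ndarray
    channel_pair: ChannelPair
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.gp.shape != self.valid.shape:
            raise ValueError("gp and valid masks must share shape")
        vals = self.gp[self.valid]
        if vals.size and (np.nanmin(vals) < -1 - 1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("valid GP values must lie in [-1, 1]")

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """GP values of valid pixels, optionally restricted to a mask."""
        sel = self.valid if mask is None else (self.valid & mask.astype(bool))
        return self.gp[sel]


def select_channels(
    stack: SpectralStack, lambda_b: float, lambda_r: float
) -> ChannelPair:
    """Pick the stack channels whose band centers are nearest λ_B and λ_R.

    Ties (a requested wavelength exactly midway between two band centers)
    break toward the bluer channel.  Requested wavelengths must lie within
    the axis range extended by half the median band spacing.
    """
    if not lambda_b < lambda_r:
        raise ValueError("lambda_b must be smaller than lambda_r")
    wl = stack.wavelengths
    half_step = 0.5 * float(np.median(np.diff(wl)))
    lo, hi = wl[0] - half_step, wl[-1] + half_step
    for lam, name in ((lambda_b, "lambda_b"), (lambda_r, "lambda_r")):
        if not (lo <= lam <= hi):
            raise ValueError(
                f"{name}={lam} nm outside axis range [{wl[0]}, {wl[-1]}] ± {half_step}"
            )
    # argmin returns the first (bluest) index on ties
    idx_b = int(np.argmin(np.abs(wl - lambda_b)))
    idx_r = int(np.argmin(np.abs(wl - lambda_r)))
    if idx_b == idx_r:
        raise ValueError(
            f"lambda_b={lambda_b} and lambda_r={lambda_r} map to the same "
            f"channel (center {wl[idx_b]} nm)"
        )
    return ChannelPair(
        lambda_b_nm=float(lambda_b),
        lambda_r_nm=float(lambda_r),
        index_b=idx_b,
        index_r=idx_r,
        actual_b_nm=float(wl[idx_b]),
        actual_r_nm=float(wl[idx_r]),
    )


def correction_factor(
    i_b_ref: float, i_r_ref: float, gp_ref: float
) -> CorrectionFactor:
    """G factor from reference-channel intensities and fluorimeter GP."""
    if not (i_b_ref > 0 and i_r_ref > 0):
        raise ValueError("reference intensities must be positive")
    if not (-1.0 < gp_ref < 1.0):
        raise ValueError(
            "degenerate reference GP: gp_ref must lie strictly inside (-1, 1)"
        )
    g = (i_b_ref * (1.0 - gp_ref)) / (i_r_ref * (1.0 + gp_ref))
    return CorrectionFactor(g=g, gp_ref=gp_ref, i_b_ref=i_b_ref, i_r_ref=i_r_ref)


def correction_factor_from_stack(
    reference: SpectralStack,
    gp_ref: float,
    lambda_b: float,
    lambda_r: float,
    window: int = 0,
) -> CorrectionFactor:
    """G factor from a reference-solution stack imaged on this instrument.

    Mean I_B and I_R are taken over all pixels of the reference stack at
    the same channel pair (and averaging window) later used for samples.
    """
    pair = select_channels(reference, lambda_b, lambda_r)
    i_b, i_r = _channel_images(reference.plane(), pair, window)
    return correction_factor(float(i_b.mean()), float(i_r.mean()), gp_ref)


def _channel_images(
    plane: np.ndarray, pair: ChannelPair, window: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Extract I_B and I_R images, optionally averaging ±window channels."""
    n_c = plane.shape[2]
    if not (0 <= pair.index_b < n_c and 0 <= pair.index_r < n_c):
        raise IndexError("channel pair indices out of range for stack")

    def band(idx: int) -> np.ndarray:
        lo, hi = max(0, idx - window), min(n_c, idx + window + 1)
        return plane[:, :, lo:hi].mean(axis=2)

    return band(pair.index_b), band(pair.index_r)


def compute_gp_map(
    stack_or_plane: SpectralStack | np.ndarray,
    pair: ChannelPair,
    g: float = 1.0,
    median_radius: int = 0,
    signal_threshold: float | str = "otsu",
    window: int = 0,
    z: int = 0,
    t: int = 0,
) -> GPMap:
    """Compute the per-pixel GP map of one (z, t) plane.

    The stack is reduced to the two images at λ_B and λ_R; each is
    optionally median-filtered with a square kernel of side
    ``2*median_radius + 1`` before the ratio.  Pixels whose combined
    signal I_B + G·I_R falls below ``signal_threshold`` (``"otsu"``: the
    Otsu level of the combined-signal image) or is non-positive are marked
    invalid.  With ``g=1`` the result is the uncalibrated two-channel GP.
    """
    if not g > 0:
        raise ValueError("g factor must be positive")
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    if isinstance(stack_or_plane, SpectralStack):
        plane = stack_or_plane.plane(z, t)
    else:
        plane = np.asarray(stack_or_plane, dtype=float)
    i_b, i_r = _channel_images(plane, pair, window)
    if median_radius > 0:
        size = 2 * median_radius + 1
        i_b = ndimage.median_filter(i_b, size=size)
        i_r = ndimage.median_filter(i_r, size=size)

    denom = i_b + g * i_r
    if signal_threshold == "otsu":
        if np.ptp(denom) == 0:
            thr = np.inf  # constant combined signal: nothing is significant
        else:
            thr = float(threshold_otsu(denom, nbins=256))
    else:
        thr = float(signal_threshold)
    valid = (denom > 0) & (denom >= thr)

    gp = np.full(denom.shape, np.nan)
    np.divide(i_b - g * i_r, denom, out=gp, where=valid)
    np.clip(gp, -1.0, 1.0, out=gp)  # guard float round-off at the bounds
    return GPMap(gp=gp, valid=valid, channel_pair=pair, g_factor=float(g))
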