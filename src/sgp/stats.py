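"""Per-region spectra, GP histograms, Gaussian fits and object summaries.

The GP histogram of a region is fitted with both a one-peak and a two-peak
Gaussian model; the model with the lower root-mean-squared error over all
bins is selected.  A well-separated two-peak fit indicates coexisting
liquid-ordered / liquid-disordered phases, while the one-peak mean tracks
changes in overall lipid order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax

from .gp import GPMap
from .io import SpectralStack
from .segmentation import CircleDetection


@dataclass
class SpectrumProfile:
    """Mean emission spectrum over a pixel mask."""

    wavelengths: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: int


@dataclass
class GaussianFit:
    """One- or two-peak Gaussian fit of a GP histogram.

    ``n_peaks`` corresponds to the candidate model with the lower RMSE;
    for two peaks, parameters are reported with means ascending.  When
    neither model converges, ``n_peaks`` is 0 and the moment estimates of
    the raw histogram are reported instead.
    """

    n_peaks: int
    amplitudes: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    rmse_1: float
    rmse_2: float

    @property
    def selected_rmse(self) -> float:
        finite = [r for r in (self.rmse_1, self.rmse_2) if np.isfinite(r)]
        return min(finite) if finite else float("nan")


@dataclass
class ObjectRecord:
    """Per-object summary row of the output spreadsheet."""

    object_id: int
    source_id: str
    area_px: int
    area_um2: float
    mean_gp: float
    gp_fit: GaussianFit | None = None
    membrane_mean_gp: float | None = None
    radius_px: float | None = None
    diameter_um: float | None = None

    def to_row(self) -> dict:
        f = self.gp_fit
        row = {
            "source_id": self.source_id,
            "object_id": self.object_id,
            "area_px": self.area_px,
            "area_um2": self.area_um2,
            "mean_gp": self.mean_gp,
            "membrane_mean_gp": self.membrane_mean_gp,
            "radius_px": self.radius_px,
            "diameter_um": self.diameter_um,
            "fit_n_peaks": f.n_peaks if f else None,
            "fit_rmse_1": f.rmse_1 if f else None,
            "fit_rmse_2": f.rmse_2 if f else None,
        }
        for i in range(2):
            have = f is not None and i < len(f.means)
            row[f"fit_mean_{i+1}"] = float(f.means[i]) if have else None
            row[f"fit_sigma_{i+1}"] = float(f.sigmas[i]) if have else None
            row[f"fit_amplitude_{i+1}"] = float(f.amplitudes[i]) if have else None
        return row


def mean_spectrum(stack: SpectralStack, mask: np.ndarray, z: int = 0, t: int = 0) -> SpectrumProfile:
    """Channelwise arithmetic mean intensity over the masked pixels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != stack.shape_yx:
        raise ValueError("mask shape does not match stack frame")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    plane = stack.plane(z, t)
    return SpectrumProfile(
        wavelengths=stack.wavelengths.copy(),
        mean_intensity=plane[mask].mean(axis=0),
        n_pixels=n,
    )


def gp_histogram(
    gpmap: GPMap, mask: np.ndarray | None = None, n_bins: int = 201
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of valid GP values over the fixed range [-1, 1].

    Returns (bin centers, counts); counts sum to the number of valid
    masked pixels.  The fixed range keeps histograms comparable across
    objects and images.
    """
    values = gpmap.valid_values(mask)
    if values.size == 0:
        raise ValueError("no valid GP pixels under the mask")
    counts, edges = np.histogram(values, bins=n_bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _gauss1(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _gauss2(x, a1, mu1, s1, a2, mu2, s2):
    return _gauss1(x, a1, mu1, s1) + _gauss1(x, a2, mu2, s2)


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _moments(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    w = counts / counts.sum()
    mu = float(np.sum(w * centers))
    var = float(np.sum(w * (centers - mu) ** 2))
    return mu, np.sqrt(max(var, 1e-6))


def _two_peak_init(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Initial means for the two-peak model.

    Uses the two highest well-separated local maxima of the lightly
    smoothed histogram, falling back to moment-based mu ± sigma.
    """
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    smooth = np.convolve(counts.astype(float), kernel / kernel.sum(), mode="same")
    (peaks,) = argrelmax(smooth, order=3)
    if len(peaks) >= 2:
        order = np.argsort(smooth[peaks])[::-1]
        best = int(peaks[order[0]])
        min_sep = max(3, len(centers) // 20)
        cand = [best] + [int(p) for p in peaks[order[1:]] if abs(int(p) - best) >= min_sep]
        if len(cand) >= 2:
            m1, m2 = sorted((centers[cand[0]], centers[cand[1]]))
            return float(m1), float(m2)
    mu, sig = _moments(centers, counts)
    return mu - sig, mu + sig


def _two_peak_degenerate(p: np.ndarray, centers: np.ndarray) -> bool:
    """Disqualify a two-peak candidate that does not describe two peaks.

    The extra parameters let the two-peak model shave RMSE off any noisy
    unimodal histogram, so a candidate is rejected when a component is
    degenerate: narrower than a histogram bin (a spike fitting one noisy
    bin), negligible in amplitude, pinned at the mean bounds, or not
    resolved from the other component (separation below twice the smaller
    width).
    """
    a1, mu1, s1, a2, mu2, s2 = p
    bin_width = centers[1] - centers[0] if len(centers) > 1 else 0.01
    if min(s1, s2) <= bin_width:
        return True
    if min(a1, a2) < 0.10 * max(a1, a2):
        return True
    if max(abs(mu1), abs(mu2)) >= 1.0 - 1e-6:
        return True
    if abs(mu1 - mu2) < 2.0 * min(s1, s2):
        return True
    return False


def fit_gp_distribution(
    centers: np.ndarray, counts: np.ndarray
) -> GaussianFit:
    """Fit 1- and 2-peak Gaussians to a GP histogram; keep the lower RMSE.

    RMSE is computed over all bins with no complexity penalty; instead, a
    two-peak candidate is disqualified outright when its components are
    degenerate (see :func:`_two_peak_degenerate`), and either model is
    disqualified on optimizer failure.
    """
    centers = np.asarray(centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.count_nonzero(counts) < 5:
        raise ValueError("histogram needs at least 5 nonzero bins for fitting")

    mu0, sig0 = _moments(centers, counts)
    a0 = float(counts.max())
    rmse1 = rmse2 = np.inf
    p1 = p2 = None

    # bounded trust-region fits: deterministic and keeps means in the GP
    # range and widths positive
    try:
        p1, _ = curve_fit(
            _gauss1,
            centers,
            counts,
            p0=[a0, np.clip(mu0, -1, 1), max(sig0, 1e-3)],
            method="trf",
            bounds=([0.0, -1.0, 1e-4], [np.inf, 1.0, 2.0]),
            maxfev=10000,
        )
        rmse1 = _rmse(counts, _gauss1(centers, *p1))
    except (RuntimeError, ValueError):
        p1 = None

    m1, m2 = _two_peak_init(centers, counts)
    try:
        p2, _ = curve_fit(
            _gauss2,
            centers,
            counts,
            p0=[
                a0,
                np.clip(m1, -1, 1),
                max(sig0 / 2, 1e-3),
                a0,
                np.clip(m2, -1, 1),
                max(sig0 / 2, 1e-3),
            ],
            method="trf",
            bounds=(
                [0.0, -1.0, 1e-4, 0.0, -1.0, 1e-4],
                [np.inf, 1.0, 2.0, np.inf, 1.0, 2.0],
            ),
            maxfev=20000,
        )
        if _two_peak_degenerate(p2, centers):
            p2 = None
        else:
            rmse2 = _rmse(counts, _gauss2(centers, *p2))
    except (RuntimeError, ValueError):
        p2 = None

    if p1 is None and p2 is None:
        return GaussianFit(
            n_peaks=0,
            amplitudes=np.array([a0]),
            means=np.array([mu0]),
            sigmas=np.array([sig0]),
            rmse_1=float("inf"),
            rmse_2=float("inf"),
        )
    if rmse1 <= rmse2:
        return GaussianFit(
            n_peaks=1,
            amplitudes=np.array([p1[0]]),
            means=np.array([p1[1]]),
            sigmas=np.array([p1[2]]),
            rmse_1=rmse1,
            rmse_2=rmse2,
        )
    order = np.argsort([p2[1], p2[4]])
    amps = np.array([p2[0], p2[3]])[order]
    means = np.array([p2[1], p2[4]])[order]
    sigmas = np.array([p2[2], p2[5]])[order]
    return GaussianFit(
        n_peaks=2,
        amplitudes=amps,
        means=means,
        sigmas=sigmas,
        rmse_1=rmse1,
        rmse_2=rmse2,
    )


def fit_gp_samples(values: np.ndarray, n_bins: int = 201) -> GaussianFit:
    """Convenience: histogram raw GP samples then fit the models."""
    counts, edges = np.histogram(values, bins=n_bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return fit_gp_distribution(centers, counts)


def summarize_object(
    gpmap: GPMap,
    object_mask: np.ndarray,
    object_id: int = 1,
    source_id: str = "stack",
    membrane_mask: np.ndarray | None = None,
    circle: CircleDetection | None = None,
    pixel_size_um: float = 1.0,
    fit: bool = True,
) -> ObjectRecord:
    """Summarize one object: area, mean GP, histogram fit, optional circle.

    ``diameter_um`` is 2 · radius_px · pixel_size_um when a circle is
    supplied; ``membrane_mean_gp`` is the mean over the membrane band.
    """
    object_mask = np.asarray(object_mask).astype(bool)
    vals = gpmap.valid_values(object_mask)
    if vals.size == 0:
        raise ValueError("object mask selects no valid GP pixels")
    area_px = int(object_mask.sum())
    gp_fit = None
    if fit:
        try:
            centers, counts = gp_histogram(gpmap, object_mask)
            gp_fit = fit_gp_distribution(centers, counts)
        except ValueError:
            gp_fit = None
    membrane_mean = None
    if membrane_mask is not None:
        mvals = gpmap.valid_values(membrane_mask)
        if mvals.size:
            membrane_mean = float(mvals.mean())
    radius = diameter = None
    if circle is not None:
        radius = float(circle.radius_px)
        diameter = 2.0 * radius * pixel_size_um
    return ObjectRecord(
        object_id=object_id,
        source_id=source_id,
        area_px=area_px,
        area_um2=area_px * pixel_size_um**2,
        mean_gp=float(vals.mean()),
        gp_fit=gp_fit,
        membrane_mean_gp=membrane_mean,
        radius_px=radius,
        diameter_um=diameter,
    )
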