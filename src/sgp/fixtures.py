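"""Synthetic spectral-stack generator with analytic ground truth.

Polarity-sensitive probes such as Laurdan shift their emission between an
ordered (blue) and a disordered (red) spectral component.  The generator
models the per-pixel emission spectrum as a two-Gaussian mixture

    I(lambda) = B * [ f * N(lambda; mu_o, sigma_o)
                    + (1 - f) * N(lambda; mu_d, sigma_d) ]

where ``f`` is the local order fraction and ``B`` a brightness constant.
Defaults (mu_o = 440 nm, mu_d = 490 nm, sigma = 25 nm) emulate
Laurdan-like spectra.  Scenes emulate membrane-localized vs internalized
probe distributions (ring-shaped membranes around dimmer, more disordered
interiors), hollow vesicle shells, touching/fused objects, and spherical
shells; Poisson shot noise and optional Gaussian read noise are applied
channelwise.  Every scene carries a SceneTruth with region labels and the
analytically expected GP at the chosen channel pair, so downstream tests
can compare pipeline output against closed-form values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SpectralStack


@dataclass(frozen=True)
class EmissionModel:
    """Two-component Gaussian emission model of a polarity probe."""

    mu_ordered_nm: float = 440.0
    sigma_ordered_nm: float = 25.0
    mu_disordered_nm: float = 490.0
    sigma_disordered_nm: float = 25.0

    def __post_init__(self) -> None:
        if not self.mu_ordered_nm < self.mu_disordered_nm:
            raise ValueError("ordered component must be bluer than disordered")
        if self.sigma_ordered_nm <= 0 or self.sigma_disordered_nm <= 0:
            raise ValueError("spectral widths must be positive")


@dataclass
class SceneTruth:
    """Ground truth for a generated scene.

    ``region_labels``: 0 = background, positive integers = objects (for
    cell scenes, membrane and interior of object k share label k;
    ``membrane_mask`` separates them).  ``expected_gp`` maps region label
    -> analytic GP at the recorded channel pair.
    """

    region_labels: np.ndarray
    order_fractions: dict[int, float]
    expected_gp: dict[int, float]
    lambda_b_nm: float
    lambda_r_nm: float
    seed: int
    membrane_mask: np.ndarray | None = None
    interior_mask: np.ndarray | None = None
    membrane_gp: float | None = None
    interior_gp: float | None = None
    circles: list[tuple[float, float, float]] = field(default_factory=list)


DEFAULT_WAVELENGTHS = np.arange(410.0, 529.0, 9.0)  # 410..527 nm, 14 bands


def spectrum_at(
    model: EmissionModel,
    f: float,
    wavelengths: np.ndarray,
    brightness: float = 1000.0,
) -> np.ndarray:
    """Expected per-channel intensities for order fraction ``f``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("order fraction must lie in [0, 1]")
    wl = np.asarray(wavelengths, dtype=float)
    no = np.exp(-((wl - model.mu_ordered_nm) ** 2) / (2 * model.sigma_ordered_nm**2))
    nd = np.exp(
        -((wl - model.mu_disordered_nm) ** 2) / (2 * model.sigma_disordered_nm**2)
    )
    return brightness * (f * no + (1.0 - f) * nd)


def expected_gp(
    model: EmissionModel,
    f: float,
    lambda_b: float,
    lambda_r: float,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
) -> float:
    """Analytic GP at the nearest channels to (lambda_b, lambda_r)."""
    wl = np.asarray(wavelengths, dtype=float)
    idx_b = int(np.argmin(np.abs(wl - lambda_b)))
    idx_r = int(np.argmin(np.abs(wl - lambda_r)))
    spec = spectrum_at(model, f, wl)
    i_b, i_r = spec[idx_b], spec[idx_r]
    return float((i_b - i_r) / (i_b + i_r))


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ring_mask(shape, cy, cx, r_out, thickness):
    outer = _disk_mask(shape, cy, cx, r_out)
    inner = _disk_mask(shape, cy, cx, r_out - thickness)
    return outer & ~inner, inner


def _apply_noise(
    expected: np.ndarray, rng: np.random.Generator, poisson: bool, read_sigma: float
) -> np.ndarray:
    out = expected
    if poisson:
        out = rng.poisson(expected).astype(float)
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def make_membrane_scene(
    kind: str = "cell",
    shape: tuple[int, int] = (128, 128),
    centers: list[tuple[float, float]] | None = None,
    radius: float = 30.0,
    membrane_thickness: float = 4.0,
    f_membrane: float = 0.7,
    f_interior: float = 0.3,
    interior_brightness: float = 0.5,
    membrane_brightness: float = 1000.0,
    background_brightness: float = 2.0,
    noise: bool = True,
    read_sigma: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    lambda_b: float = 440.0,
    lambda_r: float = 490.0,
    pixel_size_um: float = 0.5,
    model: EmissionModel = EmissionModel(),
) -> tuple[SpectralStack, SceneTruth]:
    """Cell- or vesicle-like scene: bright membrane ring, optional interior.

    ``kind="cell"`` emulates an internalized probe (interior labeled with
    order fraction ``f_interior`` at relative brightness
    ``interior_brightness``); ``kind="guv"`` produces hollow shells
    (interior brightness 0).  Multiple ``centers`` may touch, producing
    fused objects for watershed tests.  Identical seeds give bit-identical
    stacks.
    """
    if kind not in ("cell", "guv"):
        raise ValueError("kind must be 'cell' or 'guv'")
    if kind == "guv":
        interior_brightness = 0.0
    if centers is None:
        centers = [(shape[0] / 2, shape[1] / 2)]
    for cy, cx in centers:
        if not (radius <= cy <= shape[0] - radius and radius <= cx <= shape[1] - radius):
            raise ValueError("object geometry exceeds the frame")

    wl = np.asarray(wavelengths, dtype=float)
    n_c = wl.size
    labels = np.zeros(shape, dtype=np.int32)
    membrane = np.zeros(shape, dtype=bool)
    interior = np.zeros(shape, dtype=bool)
    for k, (cy, cx) in enumerate(centers, start=1):
        ring, inner = _ring_mask(shape, cy, cx, radius, membrane_thickness)
        labels[ring | inner] = k
        membrane |= ring
        interior |= inner

    spec_mem = spectrum_at(model, f_membrane, wl, membrane_brightness)
    spec_int = spectrum_at(model, f_interior, wl, membrane_brightness * interior_brightness)
    spec_bg = np.full(n_c, background_brightness)

    expected = np.empty(shape + (n_c,), dtype=float)
    expected[:] = spec_bg
    expected[interior] = spec_int
    expected[membrane] = spec_mem

    rng = np.random.default_rng(seed)
    data = _apply_noise(expected, rng, noise, read_sigma)

    gp_m = expected_gp(model, f_membrane, lambda_b, lambda_r, wl)
    gp_i = expected_gp(model, f_interior, lambda_b, lambda_r, wl)
    fractions = {k: f_membrane for k in range(1, len(centers) + 1)}
    gps = {k: gp_m for k in range(1, len(centers) + 1)}
    stack = SpectralStack(
        intensities=data,
        wavelengths=wl,
        pixel_size_um=pixel_size_um,
        source_id=f"{kind}_seed{seed}",
    )
    truth = SceneTruth(
        region_labels=labels,
        order_fractions=fractions,
        expected_gp=gps,
        lambda_b_nm=lambda_b,
        lambda_r_nm=lambda_r,
        seed=seed,
        membrane_mask=membrane,
        interior_mask=interior,
        membrane_gp=gp_m,
        interior_gp=gp_i if kind == "cell" else None,
    )
    return stack, truth


def make_spherical_scene(
    radii: list[float],
    centers: list[tuple[float, float]] | None = None,
    shape: tuple[int, int] = (128, 128),
    shell_thickness: float = 3.0,
    f_shell: float = 0.8,
    shell_brightness: float = 1000.0,
    background_brightness: float = 2.0,
    noise: bool = True,
    read_sigma: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    lambda_b: float = 440.0,
    lambda_r: float = 490.0,
    pixel_size_um: float = 0.5,
    overlap_tolerance: float = 0.0,
    model: EmissionModel = EmissionModel(),
) -> tuple[SpectralStack, SceneTruth]:
    """Scene of bright circular shells (microbubble / spherical vesicle).

    Truth records every (cy, cx, r).  Shells may touch; overlap beyond
    ``overlap_tolerance`` pixels of center distance deficit is rejected.
    """
    if centers is None:
        rng0 = np.random.default_rng(seed + 10_000)
        centers = []
        for r in radii:
            for _ in range(200):
                cy = rng0.uniform(r + 2, shape[0] - r - 2)
                cx = rng0.uniform(r + 2, shape[1] - r - 2)
                ok = all(
                    np.hypot(cy - c[0], cx - c[1]) >= r + rr + 2
                    for (c, rr) in zip(centers, radii)
                )
                if ok:
                    centers.append((cy, cx))
                    break
            else:
                raise ValueError("could not place non-overlapping shells")
    if len(centers) != len(radii):
        raise ValueError("centers and radii length mismatch")
    for (cy, cx), r in zip(centers, radii):
        if not (r <= cy <= shape[0] - r and r <= cx <= shape[1] - r):
            raise ValueError("circle exceeds the frame")
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            d = np.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if d < radii[i] + radii[j] - shell_thickness - overlap_tolerance:
                raise ValueError("shells overlap beyond tolerance")

    wl = np.asarray(wavelengths, dtype=float)
    n_c = wl.size
    labels = np.zeros(shape, dtype=np.int32)
    shell = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        dist = np.hypot(yy - cy, xx - cx)
        ring = np.abs(dist - r) <= shell_thickness / 2
        labels[ring] = k
        shell |= ring

    spec_shell = spectrum_at(model, f_shell, wl, shell_brightness)
    expected = np.empty(shape + (n_c,), dtype=float)
    expected[:] = background_brightness
    expected[shell] = spec_shell

    rng = np.random.default_rng(seed)
    data = _apply_noise(expected, rng, noise, read_sigma)

    gp_s = expected_gp(model, f_shell, lambda_b, lambda_r, wl)
    stack = SpectralStack(
        intensities=data,
        wavelengths=wl,
        pixel_size_um=pixel_size_um,
        source_id=f"spheres_seed{seed}",
    )
    truth = SceneTruth(
        region_labels=labels,
        order_fractions={k: f_shell for k in range(1, len(radii) + 1)},
        expected_gp={k: gp_s for k in range(1, len(radii) + 1)},
        lambda_b_nm=lambda_b,
        lambda_r_nm=lambda_r,
        seed=seed,
        circles=[(c[0], c[1], float(r)) for c, r in zip(centers, radii)],
    )
    return stack, truth


def make_reference_scene(
    gp_true: float = 0.0,
    shape: tuple[int, int] = (64, 64),
    brightness: float = 1000.0,
    noise: bool = False,
    seed: int = 0,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    lambda_b: float = 440.0,
    lambda_r: float = 490.0,
    model: EmissionModel = EmissionModel(),
) -> tuple[SpectralStack, float]:
    """Uniform reference-solution stack whose analytic GP equals ``gp_true``.

    Solves for the order fraction f at which the emission model's GP at
    the chosen channel pair equals ``gp_true`` (monotone in f, bisection),
    then fills the frame with that spectrum.  Returns (stack, f_solution).
    """
    wl = np.asarray(wavelengths, dtype=float)
    lo, hi = 0.0, 1.0
    g_lo = expected_gp(model, lo, lambda_b, lambda_r, wl)
    g_hi = expected_gp(model, hi, lambda_b, lambda_r, wl)
    if not (min(g_lo, g_hi) <= gp_true <= max(g_lo, g_hi)):
        raise ValueError(
            f"gp_true={gp_true} outside the model's attainable range "
            f"[{g_lo:.3f}, {g_hi:.3f}]"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_gp(model, mid, lambda_b, lambda_r, wl) < gp_true:
            lo = mid
        else:
            hi = mid
    f = 0.5 * (lo + hi)
    spec = spectrum_at(model, f, wl, brightness)
    expected = np.broadcast_to(spec, shape + (wl.size,)).copy()
    rng = np.random.default_rng(seed)
    data = _apply_noise(expected, rng, noise, 0.0)
    stack = SpectralStack(
        intensities=data,
        wavelengths=wl,
        pixel_size_um=1.0,
        source_id=f"reference_seed{seed}",
    )
    return stack, f
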