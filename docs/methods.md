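# Methods

## The GP model

Generalized polarization condenses a pixel's emission spectrum into one
number, `GP = (I_B − I_R)/(I_B + I_R)`, using the intensities at a blue
and a red wavelength chosen at the probe's ordered- and disordered-phase
emission maxima.  Only the two channels nearest λ_B and λ_R enter the
computation; the rest of the stack is used for detection (summed
intensity), spectra and nothing else.  GP is bounded in [−1, 1] by
construction for non-negative intensities, with the endpoints attained
exactly when one channel is zero.

Channel selection is *nearest band center*, not interpolation; ties
between two equally distant centers break toward the bluer channel.  An
optional window parameter averages ±k neighboring channels around each
selected channel before the ratio (default k = 0).  Per-pixel spectral
curve fitting (e.g. gamma-variate interpolation of I_B and I_R) is
deliberately not offered: it is too costly for batch work, and median
pre-smoothing of the two channel images achieves comparable noise
suppression.  The median filter is a square kernel of side
`2·radius + 1` applied to the raw I_B and I_R images *before* the ratio
and before calibration; radius 0 (the default) is the identity.

**Calibration.**  Channel gains vary between instruments, so absolute GP
uses `G = (I_B,ref (1 − GP_ref)) / (I_R,ref (1 + GP_ref))` computed from
a reference-solution image and its fluorimeter GP, applied as
`GP = (I_B − G·I_R)/(I_B + G·I_R)`.  The identity G(ref) applied back to
the reference recovers GP_ref exactly (to float precision); this
closed-form round trip is asserted to 10⁻¹² in the tests.  GP_ref = ±1
makes the formula degenerate and is rejected.

**Significant signal.**  Pixels enter histograms, spectra and means only
if their combined signal `I_B + G·I_R` is positive and at least a
threshold; the default threshold is the Otsu level of the combined-signal
image, reusing the same automatic thresholding the segmentation stage
uses rather than inventing a second criterion.  Invalid pixels carry NaN
and a False entry in the validity mask.

## Segmentation

Objects are detected on the summed-intensity image: Otsu threshold
(256-bin histogram), 8-connected component labelling, rejection of
components under `min_area` (default 50 px), bounding boxes padded by
5 px and clipped to the frame.

**Splitting touching objects.**  The Euclidean distance transform of the
object mask is negated and watershed-segmented; regional minima deeper
than h are the markers (h-minima suppression via morphological
reconstruction).  The basin count is non-increasing in h, so h is found
by monotone bisection over [0, max distance] for the largest h whose
count is still ≥ n; if the count overshoots n, surplus basins are merged
ascending by area into their largest watershed-adjacent neighbor until
exactly n remain.  This guarantees the user contract — ask for n objects,
get n labels — whenever n basins exist at h = 0; otherwise the achievable
maximum is reported in the error.  n = 1 returns the mask unchanged.  The
watershed operates on the binary mask's distance transform only, not on
intensities.

**Membrane bands without a counterstain.**  Each single-object crop is
hole-filled; the boundary is the set of filled-mask pixels with nonzero
Sobel gradient (for a binary mask this is exactly the boundary ring);
the boundary is dilated to the requested thickness and intersected with
the filled object.  The default structuring element is a disc, giving an
isotropic, equal-thickness band; a 3-px horizontal line element is
available (`element="line"`, CLI `--paper-element`) but produces an
anisotropic band and is not recommended for quantitative GUV work.
Thickness at least the object's inradius saturates to the whole object.

**Spherical objects.**  Microbubbles and spherical vesicles are found by
a circular Hough transform over the Sobel-edge map (edges above the
gradient's Otsu level).  Detection is greedy: the global accumulator
maximum (normalized by circle perimeter) is accepted if ≥ 0.5, its
supporting edge pixels (within ±3 px of the circle) are removed, and the
accumulator is recomputed; this continues until no peak reaches the
threshold.  Because a shell of finite thickness yields two edge rings at
r ± thickness/2, the radius is refined as the accumulator-weighted
centroid of the strong band (≥ 0.4 of the peak within ±5 px) of the
radius profile, which lands mid-shell; centers are refined to subpixel by
parabolic interpolation.  Touching circles are retained; residual
candidates within r_min of a kept center are suppressed.  On noiseless
rings this recovers radii within 1 px across r ∈ [5, 40].

**Scripted ROIs.**  Lasso selection is replaced by polygon ROIs supplied
as vertex lists (JSON/CSV).  A pixel belongs to the ROI iff its center is
inside the polygon or exactly on its boundary (shapely's covers
predicate); the inclusive-boundary convention makes an axis-aligned
square with corners (10,10)–(30,30) cover 21 × 21 pixels.

## GP histograms and Gaussian fits

Histograms use 201 bins over the fixed range [−1, 1] so that bin edges
and widths are identical across objects and images.  Both a one-peak
Gaussian `A·exp(−(x−µ)²/2σ²)` and a two-peak sum are fitted by bounded
trust-region least squares (means in [−1, 1], σ ∈ [10⁻⁴, 2], amplitudes
≥ 0); the trust-region path is used because it is deterministic across
repeated calls, which the byte-identical batch contract relies on.
Two-peak initialization places the means at the two highest
well-separated local maxima of a lightly smoothed histogram, falling
back to the moment estimate µ̂ ± σ̂.

Model selection takes the lower RMSE over all bins, with no complexity
penalty.  Since the richer model can always shave RMSE off a noisy
unimodal histogram, a two-peak candidate is disqualified outright when it
does not actually describe two peaks: a component narrower than one
histogram bin (a spike fitting a single noisy bin), a component below
10% of the dominant amplitude (indistinguishable from histogram noise —
the two-peak model exists to flag genuine phase coexistence, not trace
contributions), a mean pinned at ±1, or components closer than twice the
smaller width (an unresolved duplicate).  If neither model converges the
raw moments are reported with `n_peaks = 0`.  On synthetic data these
rules select one peak on ≥ 95% of unimodal replicates while recovering
both means of a −0.4/+0.4, σ = 0.05 mixture within 0.02.

## Visualization

GP maps are rendered through a 256-entry LUT linearly scaled over
[−1, 1] (`index = round((gp+1)/2 · 255)`), so color is comparable across
images; the palette defaults to a blue→green→red ramp and is
configurable — only the scaling is fixed.  Invalid pixels get a reserved
dark-gray background color that is not a LUT entry.  z-stacks assemble
into a GP volume losslessly (bit-exact slice round trip) and export as a
colored point set (x, y, z in µm + RGB) and a multi-page RGB TIFF.

## Synthetic scenes (the test substrate)

The generator models a polarity probe's emission as a two-Gaussian
mixture, `I(λ) ∝ f·N(λ; µ_o, σ_o) + (1−f)·N(λ; µ_d, σ_d)`, with
defaults µ_o = 440 nm, µ_d = 490 nm, σ = 25 nm emulating Laurdan-like
spectra, sampled on a 410–527 nm axis in 9 nm bands.  The order fraction
f sets the expected GP analytically, so every scene carries closed-form
ground truth at the chosen channel pair.

Scenes emulate the study conditions: 128×128 frames at 0.5 µm/px; cells
as a bright membrane ring (radius 30 px, thickness 4 px, f = 0.7) around
an internalized-probe interior (f = 0.3 at half brightness); GUVs as
hollow shells; spherical scenes as thin bright shells with recorded
centers/radii; a uniform reference scene solves for the f that attains a
requested GP (bisection — the GP of the model is monotone in f, range
about ±0.76 at 440/490 nm).  Brightness defaults to 1000 expected counts
(photon-rich imaging); noise is channelwise Poisson on the expected
counts plus optional Gaussian read noise, all seeded — identical seeds
give bit-identical stacks.  Where a specific signal-to-noise ratio is
wanted, brightness is set so the brightest channel expects SNR² counts
(Poisson SNR = √counts at the peak).

What the generator does *not* emulate: the microscope PSF (no optical
blur), photobleaching, spectral detector crosstalk, autofluorescence, or
non-spherical cell shapes.  Passing tests therefore demonstrate
correctness of the computation and robustness to shot noise, not
performance on aberrated or low-magnification real data.

## Pipeline and determinism

Hyperstacks are processed per (z, t) plane independently; volumes are
assembled per time point.  Batch runs process every matched file
independently, log and skip per-file failures, and concatenate records
sorted by (source, object id).  The summary CSV is written with floats at
full precision (`%.17g`); all randomness is seeded and every fit is
deterministic, so re-running a batch reproduces the CSV byte for byte.
Interactive review steps are replaced by configuration: per-crop object
counts come from a config map, and exclusions are explicit
`source_id:object_id` entries, never inferred.

## Problem sizes in the acceptance script

The acceptance script measures: GP range on a 201×201 intensity grid;
calibration round trip at five reference GPs; 20 overlapping-disc
geometries for the exact-n watershed; 50 three-shell scenes (160×160,
Poisson SNR 10) for Hough radius recovery; 50 replicates each of the
unimodal (10⁴ samples) and −0.4/+0.4 mixture (10⁴ samples) fits; 10
noiseless and 40 SNR-5 cell scenes for the membrane-band benefit; and a
3-stack batch run twice for byte-identical output.  These sizes keep the
full script under a minute on one CPU while leaving the success criteria
statistically meaningful.

## Known limitations

- TIFF/OME-TIFF only; proprietary microscope formats must be converted
  upstream.  RGB (sample-interleaved) TIFFs are accepted only when the
  samples are the spectral channels.
- Wavelengths absent from both metadata and overrides are an error — the
  package never guesses an emission axis.
- The watershed split assumes roughly convex, comparably sized objects;
  strongly non-convex cells are better served by polygon ROIs.
- The equal-thickness membrane band assumes the probe labels the
  outermost boundary; internalized bright organelles adjacent to the
  membrane will leak into the band.
- Circle detection assumes shells/discs with reasonably complete edges;
  heavily occluded bubbles (> half the perimeter missing) fall below the
  0.5 accumulator threshold.
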