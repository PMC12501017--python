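# Methods

## Signal model and angiography reconstruction

A 4D acquisition is an intensity array I(t, z, y, x) with at least two
frames and physical voxel spacing (dz, dy, dx) in micrometers. The
angiogram is the mean pairwise amplitude decorrelation

D = (1/(N−1)) Σₙ [ 1 − 2·Iₙ·Iₙ₊₁ / (Iₙ² + Iₙ₊₁²) ]

over the N−1 consecutive frame pairs. Each pair term is 1 minus the
ratio of the geometric to the quadratic mean of the two intensities, so
it lies in [0, 1], is exactly 0 for identical frames, 1 when exactly one
intensity of a pair is zero, and is invariant to any global intensity
rescaling. Two conventions are fixed deliberately:

* a pair with both intensities zero contributes 0 — darkness is absence
  of evidence for flow, not evidence of flow;
* voxels whose time-mean intensity falls below the noise floor (default:
  the 0.5 quantile of the time-mean distribution, linear-interpolation
  percentile) are flagged and forced to D = 0, because decorrelation of
  noise-dominated voxels is meaningless and downstream thresholding
  assumes dark static background.

Full-spectrum amplitudes only; no spectral splitting and no inter-frame
registration (the phantoms are motion-free, and motion correction is out
of scope).

## The phantom generator

The generator emulates exactly the features the pipeline consumes, and
nothing else:

* **Background**: one static log-normal speckle field (default mean 100,
  coefficient of variation 0.2), replicated across frames with a small
  multiplicative sensor-noise term (CV 0.02). Its inter-frame
  decorrelation is O(10⁻³)–O(10⁻⁴).
* **Lumens**: tubes defined by centerline control points and a radius; a
  voxel belongs to a lumen iff its center lies within the radius of the
  centerline polyline. Lumen voxels carry fully developed dynamic
  speckle: the per-frame complex reflectance is
  gₙ = √(1−w)·g₀ + √w·eₙ with g₀ static and eₙ fresh circular-Gaussian
  draws, and the intensity m·|gₙ|² is exponentially distributed with
  mean = background mean × contrast (default contrast 3).
* **Calibration**: the expected pairwise decorrelation is a strictly
  increasing function of the renewal weight w, from 0 at w = 0 to
  2 − π/2 ≈ 0.429 at w = 1 (closed form for independent exponential
  intensities). The curve itself has no convenient closed form at
  intermediate w, so it is estimated once on a fixed deterministic
  Monte-Carlo sample (2×10⁵ draws, internal fixed seed) and inverted by
  bisection. Measured lumen decorrelation lands within ±0.01 of the
  requested target (tolerance contract: ±0.05). Targets above the
  w = 1 ceiling are physically unreachable in this model and rejected at
  validation; the default target is 0.4.
* **Geometry defaults**: anisotropic voxels (8, 4, 4) µm to force
  physical-unit handling; eight frames. Tube axes are placed a quarter
  voxel off the voxel-center lattice: axes on voxel centers or on voxel
  faces are the two worst cases for rasterizing a circle, aliasing both
  the across-tube voxel extent (the FWHM ground truth) and the disc
  voxel count (the area ground truth) by >10 % at small radii, while the
  quarter-voxel offset keeps both within a few percent for radii ≥ 2
  voxels. Tubes span the grid face to face so the skeleton is not
  shortened by rounded end caps.
* **Determinism**: a single integer seed drives one `numpy` Generator;
  identical spec + seed gives byte-identical volumes.

What the phantom does **not** model: bulk-tissue motion, galvo
artifacts, shadowing and depth attenuation, multiple scattering,
projection artifacts, partial-volume flow at lumen boundaries (lumen
membership is binary). Passing recovery tests therefore demonstrates
correctness of the measurement chain on ideal, motion-free data — not
robustness to the artifacts of in vivo acquisition.

## Tubular enhancement

Standard 3D ridge (vesselness) filtering of the decorrelation volume.
The Hessian at physical scale σ is computed by Gaussian-derivative
smoothing with per-axis sigmas σ/spacing in voxel units (no resampling),
converted to physical 1/µm² and multiplied by σ² (γ = 2), so responses
are comparable across scales. scipy's truncated second-derivative
kernels do not sum exactly to zero; the residual (a multiple of the
smoothed volume) is subtracted explicitly so constant volumes have an
exactly zero Hessian. Eigenvalues are sorted by magnitude
|λ₁| ≤ |λ₂| ≤ |λ₃| and combined into the usual three-factor bright-tube
functional with α = β = 0.5 and c either fixed or "auto" = half the
maximum structure norm S at that scale. Voxels with |λ₃| below an
absolute floor of 10⁻¹⁰ are treated as unstructured, so the
data-adaptive c cannot normalize machine noise into signal. The response
is the maximum over the scale ladder (default 7.5/15/30/60 µm, a
geometric ladder bracketing 0.5–2× the radii implied by a 15 µm
resolution floor and tumor vessel sizes); ties in the argmax take the
smallest scale. The pipeline drops — with a logged warning — any ladder
scale smaller than the largest voxel dimension, where the derivative
kernel would be undersampled (with the default (8, 4, 4) µm spacing the
7.5 µm rung is dropped).

Enhancement runs on the 3D decorrelation volume, not on an en-face
projection and not on structural intensity: flow contrast is the
quantity the angiogram isolates.

## Lumen segmentation

"Adaptive thresholding" is realized as: voxel kept iff
value > local Gaussian-weighted mean + offset × (global max − min), with
the local mean at physical standard deviation window/2 per axis
(defaults: window 120 µm, offset 0.05). Two gates are intersected with
the thresholded flow volume:

* an absolute flow floor, D > 0.05. Both the adaptive threshold (via the
  global range) and the auto-c vesselness are *relative* criteria; on a
  volume with no flow at all they amplify sensor-noise decorrelation
  (O(10⁻³)) into spurious lumens. Perfused voxels decorrelate at
  O(0.1–0.4), so 0.05 separates the regimes with wide margins on both
  sides.
* the support of the vesselness response (> 0.01, dilated by 8 µm), so
  only flow backed by tubular evidence survives. The threshold itself
  runs on the decorrelation volume because that is where the lumen
  boundary lives; thresholding the vesselness response instead would
  shrink lumens toward their axes and bias areas low.

Cleanup: morphological closing with an 8 µm ellipsoid (physical radius
on the anisotropic grid), then removal of 26-connected components
smaller than 10⁴ µm³. The operator curation implied by a "semi-automated"
workflow is replaced by these deterministic rules; the pipeline is fully
automated.

## Centerline graphs

Thinning on an anisotropic grid distorts the medial axis, so the mask is
resampled (nearest neighbor) to isotropic voxels at the smallest voxel
dimension, thinned to a one-voxel skeleton, and mapped back to physical
micrometers. Skeleton voxels with a 26-neighbor count ≠ 2 become nodes;
clusters of adjacent node voxels merge into one node at their centroid;
maximal degree-2 chains become polyline edges with arc lengths summed in
physical units. Terminal spurs shorter than the pruning length (default
40 µm, about one large-vessel radius) are removed iteratively, except
isolated edges — whole vessels are never pruned as spurs — and
pass-through nodes left at degree 2 are merged away. The skimage Lee
thinning erases components only one or two voxels thick outright (they
contain no unremovable center voxel); such line-like components are
rescued by tracing per-bin centroids along their leading principal
direction.

## Morphometry

Every edge is resampled every 10 µm of arc length. At each sample the
local tangent is the leading principal direction of a ±3-point window
(least squares), oriented along the edge, completed to a right-handed
frame by two orthonormal normals. Diameter is measured on the
decorrelation volume — the flow image — as the FWHM of trilinear
profiles along the two normals: baseline = profile minimum, half level
halfway to the global maximum, width between the outermost interpolated
half-crossings bracketing the peak; a profile that never falls to the
half level on a side is unresolved and returns NaN. Profiles are
smoothed with a one-sample Gaussian before the crossing search (a
symmetric kernel leaves step-edge crossings in place while damping
speckle spikes that would pull the half level up and bias widths low).
Because skeleton points wander off the true axis by up to a voxel and an
off-axis profile measures a shortened chord, each sample is recentered:
measure along n₁, shift to the chord midpoint, measure along n₂ through
it (the perpendicular bisector of a chord passes through the center of a
circular cross-section), recenter again and remeasure along n₁.

Cross-sectional area comes from the binary mask: nearest-neighbor
samples on a grid in the plane perpendicular to the tangent, counting
only points 8-connected in-plane to the center so other vessels crossing
the patch are excluded, times step². The default step is one fifth of
the smallest voxel dimension: offsets k·(d/5) from a voxel-centered
point never coincide with half-voxel faces, where nearest-neighbor
rounding of boundary rows becomes inconsistent under slight tangent tilt
and inflates the count by up to one row per side (measured +12 % on a
16-voxel-wide tube at step d/2).

Per-segment diameter and area are medians over valid samples; segments
with no valid sample are dropped and logged. The resolution filter keeps
segments with diameter strictly > 15 µm (default), matching the
instrument's stated resolution floor; one graph edge counts as one
vessel.

## Endpoints

En-face convention (the standard for OCT angiography readouts; the
alternative volumetric definitions are selectable via
`density_convention="volumetric"`):

* vessel length density = Σ retained arc length (mm) / en-face field
  area (ny·dy × nx·dx, mm²);
* perfused vessel area fraction = area of the z-max projection of the
  retained segments' mask components / field area. A 26-connected mask
  component is retained iff it contains at least one retained segment's
  centerline point;
* mean diameter is length-weighted; n_vessels counts retained edges.

## Group statistics

Two groups: unpaired two-sided Student's t-test with pooled variance
(Welch behind a flag). Three or more: one-way ANOVA with a Tukey HSD
pairwise table (α = 0.05). Both SD and SEM are reported per group, since
study reports commonly mix the two. Degenerate input — all groups
constant and equal — returns p = 1 by convention. No correction is
applied across metrics. The power/calibration simulation draws
per-animal summary values directly from normal distributions
(control mean µ, treated µ·(1−effect), SD = CV × own mean, default
CV 15 % — the between-animal variability scale observed on repeated
phantom pipelines) rather than re-running the image pipeline per
replicate; at n = 5 per arm a 40 % reduction in vessel length density is
detected with power > 0.95, and the null rejection rate calibrates to
0.05.

## Problem sizes and defaults

Recovery phantoms use 5 µm isotropic voxels, eight frames, tubes of
20–80 µm diameter spanning ~0.6 mm, grids of roughly 40×100×120 voxels;
the length-density phantom uses a full 1 mm × 1 mm en-face field
(200×200). The default study phantom is (8, 4, 4) µm anisotropic with
25/40/60 µm vessels. These sizes exercise every code path (anisotropy,
multi-scale response, sub-voxel placement) while keeping a full pipeline
run in seconds.

## Known limitations

* The decorrelation target of a phantom tube cannot exceed 2 − π/2
  ≈ 0.429, the independent-exponential ceiling of the renewal speckle
  model; real OCTA decorrelation values in vessels sit well inside this
  range.
* Diameters below ~3 voxels are dominated by rasterization quantization;
  the 15 µm filter (3 voxels at 5 µm) sits exactly at this limit by
  design.
* FWHM on the flow image carries a small negative bias (≈1–3 µm) from
  speckle-elevated profile maxima; it is well inside the one-voxel
  tolerance at the grids above.
* Skeleton end erosion shortens each vessel by up to ~half a radius at
  open ends; spanning tubes avoid it in phantoms, but real vessels
  ending inside the volume lose a little length.
* The statistics module assumes one summary value per animal;
  aggregation across multiple fields per animal is the caller's
  responsibility.
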