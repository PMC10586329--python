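# Methods

## Data model and geometry

All volumetric data are `(z, y, x)` grids with an isotropic voxel size in
μm, `z` being the slice axis of a TIFF stack.  Voxel centers sit at
half-integer physical offsets: voxel `(i, j, k)` is centered at
`origin + (index + 0.5)·h`.  Centroids, distances and ROI widths are always
physical (μm), so results are invariant to resampling.  TIFF carries no
spacing and requires it from the caller; NIfTI stores the voxel size in the
affine (μm, `xyzt_units = micron`) and the stored value takes precedence on
read unless explicitly forced.

## Preprocessing

Reconstructed volumes are downscaled by 0.5 with trilinear interpolation
(each output voxel sampled at its physical position in the input grid;
constants and linear ramps are reproduced exactly), doubling the voxel size.
Low-order shading is then removed per slice by least-squares fitting the
full bivariate quadratic `a₀ + a₁x + a₂y + a₃x² + a₄xy + a₅y²` — the richest
standard 2D quadric, matching common background-flattening practice — and
subtracting it re-centered at its grand mean, so the intensity scale (and
hence the histogram mode) is preserved.  Slices with fewer than six usable
voxels inherit the nearest fitted slice's coefficients.  Subtraction (not
division) is used: phase-contrast shading is additive in the reconstruction.

Tissue statistics for thresholding are robust by construction: the mode is
the center of the maximal bin of a 256-bin histogram spanning the 0.1–99.9
percentile range (hyperintense inclusions and outliers cannot move it), the
SD is the plain standard deviation.  With n = 64³ Gaussian voxels the mode
estimate is reproducible to ~1 intensity unit (the histogram argmax wanders
over the few bins whose expected counts differ by less than shot noise —
this sampling limit, not the bin width, sets the tolerance used in tests).
The statistics mask is an explicit argument; whether the original analysis
used the whole volume or the tissue mask is not derivable, so the package
makes the choice visible at the call site.

## Granule detection

A voxel is foreground iff it exceeds `mode + 4.5·SD` and is connected
through such voxels to at least one voxel above `mode + 6·SD`.  Connectivity
is 26 for both the hysteresis rule and component labeling (the default of
the common 3D analysis plugins; the original tool's choice is unpublished).
The implementation is verified against a brute-force BFS of the definition
on random fields and is monotone in both thresholds.

Morphometry per component: volume `V = n·h³`; centroid as the mean of voxel
centers; surface area by the Crofton formula with 13 discrete directions
(3 axes, 6 face diagonals, 4 body diagonals, weighted by the spherical
Voronoi measure of each direction; transitions counted on the padded crop);
sphericity `Ψ = 36πV²/S³`; equivalent spherical diameter `d = (6V/π)^{1/3}`.
Components touching the volume boundary are kept but flagged.

**Why Crofton.**  Voxel-face counting overestimates the surface of smooth
objects by up to 50%, which would push genuine spheres far below the
`Ψ > 0.85` cut.  The 13-direction Crofton estimator is accurate to ~1% on
digitized balls of ≥ 10 voxel diameter — the object class the filter must
pass.  Its known limitation: flat facets aligned with the grid axes are
underestimated by ~7% (the 13-direction Cauchy quadrature of the mean
projected area gives 5.56·a² instead of 6·a² for an axis-aligned cube), so
cubes score Ψ ≈ 0.72 at 20 voxels (asymptotically ≈ 0.66) rather than
π/6 ≈ 0.52.  This bias is irrelevant for quasi-spherical granules but is
asserted and documented in the calibration tests.  Alternatives examined
(marching-cubes mesh area with and without smoothing, total variation of a
smoothed indicator, normal-weighted face counting) trade the sphere accuracy
for the facet accuracy or vice versa; none achieves a few-percent error on
both, and sphere accuracy is what the filter depends on.

**Filter.**  Granules are components with `V > 365 μm³` and `Ψ > 0.85`,
both strict.  The volume cut is canonical in physical units: a 55-voxel
count at 2 μm voxels would be 440 μm³ and would not reproduce the 8.87 μm
minimum diameter that `(6·365/π)^{1/3}` yields exactly.  The cut excludes
oligodendrocytes (≤ ~8 μm), which also appear as small hyperintense spheres.

## Density, ROI and size statistics

The density metric at a coordinate is `Σᵢ exp(−distᵢ²/(2σ²))` over the
k = 5 nearest granule centroids, σ = 50 μm; values lie in (0, k] and the
unit is arbitrary (the map is for visualization).  It is evaluated on a
configurable coarse grid (default 10 μm spacing) rather than every voxel;
with fewer than k granules the sum runs over those available; k-NN ties are
resolved by the index ordering of the spatial tree, which is deterministic
for a fixed catalog.  A brute-force implementation must agree to 1e−9 and
does in the tests.

ROI densities are centroid-in-mask counts divided by the mask volume in
mm³ — membership by centroid, not partial overlap, to match count-based
units.  The midline band ROI selects tissue columns whose x-centers lie in
the half-open 1.6 mm interval around a given midline.  Size histograms bin
equivalent diameters (default 1 μm bins, configurable; the original bin
width is unpublished) and are normalized by the largest bin.

The package embeds the published per-subject CA densities (count/mm³):
dmPAG 855 / 1020 / 4197 (subjects 1, 3, 4) and superior colliculus
150 / 217 / 340 / 315 (subjects 1–4).  The per-subject dmPAG/colliculus
ratios are 5.7, 3.0 and 13.3; the minimum is 3.0, i.e. the dmPAG carries at
least a threefold density.  The printed cohort means of that table are not
the arithmetic means of the printed per-subject values, so no derived
quantity uses them.

## Vessel segmentation and CA–vessel contact

Granule voxels are first replaced by the tissue mode (inpainting): granules
sitting on a vessel wall otherwise dominate the local edge response and
erase the true vessel–tissue boundary.  On a constructed scene with granules
on the rim, boundary recall rises from ~0.75 to ~0.92 with inpainting.

Segmentation: 3D median filter (window 2r+1, default r = 2 voxels) →
gradient magnitude of a Gaussian-derivative filter (σ = 1 voxel; the Deriche
recursive filter is an IIR approximation of the same operator, and the
package uses the Gaussian form directly) → hysteresis on the gradient
magnitude at percentile thresholds → morphological closing (ball, r = 2) →
cavity fill → removal of components below 10⁴ μm³.  The cavity fill is
applied slicewise along each axis and combined, because a plain 3D hole fill
cannot fill a tubular lumen that exits the volume.  Percentile thresholds
make the result invariant to constant intensity offsets.  The high/low
percentile defaults (99.5, 97) were calibrated on tube phantoms: a low
threshold admitting more than ~3% of voxels crosses the 26-connected
site-percolation threshold, so the noise field attaches to the vessel shell
and leaks; at the defaults, a 20 μm tube in 1·SD noise is recovered with
0.97 recall and < 1% leakage.  All post-processing parameters are exposed in
`VesselParams` and recorded with results.

Contact is component-level: a granule touches the vasculature when its
labeled component overlaps ≥ 1 voxel of the vessel mask, optionally dilated;
the contact fraction is the percentage of cataloged granules in contact, and
is monotone in the dilation radius.

For 2D histology, candidates are 8-connected regions satisfying either
rule — channel mean > 205 with area > 5,000 μm² (open, tissue-free lumina)
or red channel < 5 with area > 1,000 μm² (blood-filled vessels).  Regions
caused by the aqueduct or tissue tears are *not* removed automatically;
that curation was manual in the original workflow and is out of scope.

## R2* relaxometry

Per voxel, nonlinear least squares of `M²(t) = A·exp(−r·t)` on the squared
magnitude, initialized from the log-linear fit (exact at zero noise) and
refined by vectorized Gauss–Newton on `(ln A, r)`.  Because squared
magnitude decays at twice the magnitude rate, the reported rate is
R2\* = r/2; the factor is a parameter (`rate_factor`) since the
squared-magnitude convention admits the direct reading as well.  Voxels with
non-positive first-echo signal, divergent iterations or negative rates are
flagged invalid (NaN).  Under Rician noise `E[M²] = s² + 2σ²`, so the noise
floor biases late echoes upward; at SNR 50 with 8 echoes (4–32 ms) the
median bias at R2\* = 40 s⁻¹ is ≈ −0.3% (the small negative net bias comes
from the log-linear weighting of late echoes), well within the 2% tolerance
asserted in tests.  Echo times are always explicit arguments.  QSM
(unwrapping, background-field removal, dipole inversion) is out of scope:
those are published third-party algorithms.

## Phantoms: what they emulate, and what they do not

The μCT phantom reproduces the *statistical* structure the pipeline relies
on: tissue background with a well-defined mode and SD, additive Gaussian
noise (post-reconstruction noise), per-slice quadratic shading, granules as
antialiased solid spheres with lognormal diameters clipped to [2, 40] μm at
8·SD contrast (a package choice — the real CA contrast in intensity units is
not published — placed comfortably above the 6·SD seed threshold), and
vessels as straight or single-bend tubes with a hypointense lumen (−4·SD)
and a bright rim (+4·SD, 2 voxels).  Sphere antialiasing by fractional
boundary coverage makes voxelized volumes unbiased, so diameter-recovery
regressions have slope 1 when detection is unbiased.  Granule centers are
pairwise separated by the sum of radii plus two voxels; object placement is
rejection sampling bounded at 10⁴ attempts with a capacity error naming the
progress.  Identical seeds give bit-identical output.

Not emulated: reconstruction physics (phase retrieval, ring artifacts),
textured tissue heterogeneity, vascular trees and branching, non-spherical
or clustered CA (the merged-CA condition that defeated vessel separation in
one subject of the original study), and histology staining texture.  Passing
recovery tests therefore demonstrates correctness of the *algorithms* under
the stated noise model, not performance on arbitrary real data.

## Problem sizes and numerical choices

Recovery tests use 100-granule phantoms of 200³ voxels at 2 μm (the working
resolution after the half-downscale), 20 seeds in the calibration suite and
5 in the acceptance script; the full-resolution path (1 μm, downscale, then
detect) is exercised at 192³.  These sizes give Poisson/regression error
bars several times tighter than the asserted tolerances while keeping each
run in seconds.  Degenerate inputs are defined errors, not silent defaults:
empty masks, non-increasing echo times, anisotropic NIfTI spacing and
out-of-range slabs all raise typed exceptions; the empty *detection* mask is
the one sanctioned exception and yields an empty catalog.  All library
randomness flows through `numpy.random.Generator` seeds carried in the specs.

## Known limitations

- Sphericity from Crofton-13 is accurate on quasi-spheres but biased high on
  axis-aligned polyhedra (facet underestimation), as documented above.
- The hysteresis/morphometry stack assumes isotropic voxels throughout.
- Vessel post-processing parameters are phantom-calibrated package choices;
  the original study's values are unpublished, so agreement with it on real
  data cannot be claimed.
- Density maps use centroids only; granule extent is ignored.
- Contact fractions depend on the vessel mask's rim convention; masks from
  other tools should be dilated explicitly rather than assumed compatible.
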