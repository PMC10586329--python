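# catomo

Detection and spatial characterization of **corpora amylacea** (CA) —
polyglucosan granules that accumulate in the aging human brain — in 3D
phase-contrast X-ray microtomography volumes, with companion tools for
vessel association and R2\* relaxometry.  The package is aimed at
neuroimaging and bioimage-analysis researchers who want a tested, scriptable
implementation of the full granule pipeline, validated end to end on
synthetic phantoms with exhaustive ground truth.

## What it computes

CA appear in phase-contrast μCT as hyperintense, quasi-spherical blobs of up
to ~30 μm diameter over the tissue background.  The pipeline:

1. **Preprocessing** (`catomo.preprocess`) — half-resolution downscale by
   trilinear interpolation; per-slice removal of low-order shading by a full
   bivariate quadratic fit; robust tissue statistics (histogram mode *m* and
   SD *s*).
2. **Detection** (`catomo.granule_detect`) — hysteresis thresholding with
   high/low thresholds *m* + 6·*s* and *m* + 4.5·*s* (a voxel is foreground
   iff it exceeds the low threshold and is 26-connected to a voxel above the
   high one), then per-component morphometry:

   - volume `V = n_voxels · h³`,
   - surface `S` by the 13-direction Crofton estimator,
   - sphericity `Ψ = 36π V² / S³`,
   - equivalent spherical diameter `d = (6V/π)^{1/3}`,

   keeping components with `V > 365 μm³` **and** `Ψ > 0.85`.  The volume cut
   corresponds to a minimum diameter of 8.87 μm, above the size range of
   oligodendrocytes.
3. **Spatial statistics** (`catomo.spatial_stats`) — Gaussian 5-NN density
   `Σᵢ exp(−distᵢ²/(2σ²))` with σ = 50 μm; ROI densities in count/mm³
   including a 1.6 mm midline band; max-normalized diameter histograms; and
   the published per-subject dmPAG vs superior-colliculus density table with
   its ≥ 3-fold ratio.
4. **Vasculature** (`catomo.vasculature`) — CA-aware vessel segmentation
   (granule inpainting at the tissue mode, median filter, Gaussian-derivative
   gradient, percentile hysteresis, closing + cavity fill + size filter), the
   CA–vessel contact fraction, and the 2D histology candidate rules
   (RGB mean > 205 & area > 5,000 μm²; red < 5 & area > 1,000 μm²).
5. **Relaxometry** (`catomo.relaxometry`) — voxelwise R2\* from multi-echo
   magnitude data by nonlinear least squares of `M²(t) = A·exp(−r·t)`, with
   R2\* = r/2.
6. **Phantoms** (`catomo.phantom`) — seeded generators for all three
   modalities with exhaustive ground truth; every quantitative claim in the
   test suite is scored against construction-time truth.

## Worked example

```python
import numpy as np
from catomo import phantom, granule_detect
from catomo.preprocess import downsample_half, fit_background, remove_background

spec = phantom.PhantomSpec(
    shape=(192, 192, 192), voxel_size=1.0,     # 1 μm reconstruction
    n_granules=40, diameter_range=(10.0, 30.0),
    granule_contrast=8.0, noise_sd=5.0, seed=42,
)
vol, truth = phantom.generate_phantom(spec)

small = downsample_half(vol)                    # 2 μm working resolution
corrected = remove_background(small, fit_background(small))
catalog = granule_detect.detect(corrected)

m = phantom.match_catalog_to_truth(catalog, truth)
print(len(catalog), m["sensitivity"], m["n_false_positives"])
```

prints `40 1.0 0`: all 40 granules of the phantom are recovered with no
false positives.  The same flow, plus density maps, ROI statistics, vessel
analysis and R2\* recovery, is scripted in `analysis/01…05`; for example
`python analysis/04_vessel_analysis.py` reports

```
tube segmentation: recall 0.970, leakage 0.007
contact fraction 7.0% (boundary recall 0.75 raw → 0.92 inpainted)
histology: 3/3 open lumina, 2/2 blood-filled vessels
```

— the inpainting numbers quantify why granules must be removed before edge
detection: with CA sitting on the vessel wall, a fifth of the true boundary
is otherwise lost.

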