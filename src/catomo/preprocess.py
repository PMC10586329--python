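"""Preprocessing of reconstructed phase-contrast volumes.

The granule pipeline works on half-resolution data: the 1 μm reconstructions
are downscaled by a factor of 0.5 with trilinear interpolation, then per-slice
low-order intensity shading is removed by fitting a full second-degree
bivariate polynomial to each slice and subtracting it (re-centered at the
model's grand mean so the intensity scale, and hence the histogram mode, is
preserved).  Robust mode/SD estimates of the tissue intensity feed the
hysteresis thresholds of the detection stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .errors import DomainError, GeometryError
from .volume_io import BinaryMask, Volume3D

__all__ = [
    "BackgroundModel",
    "downsample_half",
    "fit_background",
    "remove_background",
    "robust_stats",
]


def downsample_half(vol: Volume3D) -> Volume3D:
    """Downscale by a factor of 0.5 using trilinear interpolation.

    Output axes are ``floor(n / 2)`` and the voxel size doubles; each output
    voxel center is sampled at its physical location in the input grid, so
    constants and linear ramps are reproduced exactly (up to the half-voxel
    border) and the physical extent is preserved within one output voxel.
    """
    shape = vol.shape
    if min(shape) < 2:
        raise DomainError(f"cannot halve a degenerate axis: shape {shape}")
    out_shape = tuple(s // 2 for s in shape)
    # output voxel center j maps to input index coordinate 2j + 0.5
    coords = np.meshgrid(
        *(2.0 * np.arange(n) + 0.5 for n in out_shape), indexing="ij", sparse=True
    )
    data = ndi.map_coordinates(
        vol.data.astype(np.float64), np.broadcast_arrays(*coords), order=1, mode="nearest"
    )
    return Volume3D(data=data, voxel_size=2.0 * vol.voxel_size, origin=vol.origin)


def _design_matrix(ny: int, nx: int) -> np.ndarray:
    """Terms [1, x, y, x², xy, y²] on normalized pixel coordinates."""
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    return np.stack(
        [np.ones_like(x), x, y, x * x, x * y, y * y], axis=-1
    ).reshape(-1, 6)


@dataclasses.dataclass
class BackgroundModel:
    """Per-slice full bivariate quadratic background.

    ``coefficients[i]`` holds (a0, a1, a2, a3, a4, a5) of
    ``a0 + a1·x + a2·y + a3·x² + a4·xy + a5·y²`` for slice ``i``, with x the
    column and y the row pixel index of that slice.
    """

    coefficients: np.ndarray  # (n_slices, 6)
    slice_shape: tuple[int, int]

    def evaluate(self) -> np.ndarray:
        """Render the model as a volume of shape (n_slices, ny, nx)."""
        ny, nx = self.slice_shape
        design = _design_matrix(ny, nx)
        vals = design @ self.coefficients.T  # (ny*nx, n_slices)
        return vals.T.reshape(len(self.coefficients), ny, nx)


def fit_background(vol: Volume3D, mask: BinaryMask | None = None) -> BackgroundModel:
    """Least-squares fit of a second-degree polynomial to each slice.

    Slices with fewer than 6 in-mask voxels reuse the nearest fitted slice's
    coefficients.  An empty mask overall is a domain error.
    """
    nz, ny, nx = vol.shape
    if mask is not None:
        if mask.data.shape != vol.shape:
            raise GeometryError("mask shape does not match volume")
        m = mask.data
        if not m.any():
            raise DomainError("background fit requires a non-empty mask")
    else:
        m = np.ones(vol.shape, dtype=bool)
    design = _design_matrix(ny, nx)
    coeffs = np.full((nz, 6), np.nan)
    fitted = []
    for i in range(nz):
        sel = m[i].ravel()
        if np.count_nonzero(sel) < 6:
            continue
        a, *_ = np.linalg.lstsq(design[sel], vol.data[i].ravel()[sel].astype(np.float64), rcond=None)
        coeffs[i] = a
        fitted.append(i)
    if not fitted:
        raise DomainError("no slice has enough in-mask voxels for a 6-term fit")
    fitted_arr = np.asarray(fitted)
    for i in range(nz):
        if np.isnan(coeffs[i, 0]):
            coeffs[i] = coeffs[fitted_arr[np.argmin(np.abs(fitted_arr - i))]]
    return BackgroundModel(coefficients=coeffs, slice_shape=(ny, nx))


def remove_background(vol: Volume3D, model: BackgroundModel) -> Volume3D:
    """Subtract the fitted background, re-centered at its grand mean.

    ``out = vol − model + mean(model)`` keeps the overall intensity scale so
    that mode/SD statistics of the corrected volume remain meaningful.
    """
    bg = model.evaluate()
    if bg.shape != vol.shape:
        raise GeometryError(
            f"background model shape {bg.shape} does not match volume {vol.shape}"
        )
    out = vol.data.astype(np.float64) - bg + bg.mean()
    return Volume3D(data=out, voxel_size=vol.voxel_size, origin=vol.origin)


def robust_stats(vol: Volume3D, mask: BinaryMask) -> tuple[float, float]:
    """Histogram mode and standard deviation of in-mask intensities.

    The mode is the center of the maximal bin of a 256-bin histogram spanning
    the 0.1–99.9 percentile range (robust against hyperintense inclusions and
    outliers); the SD is the plain standard deviation of in-mask voxels.
    """
    if mask.data.shape != vol.shape:
        raise GeometryError("mask shape does not match volume")
    values = vol.data[mask.data]
    if values.size == 0:
        raise DomainError("robust_stats requires a non-empty mask")
    values = values.astype(np.float64)
    lo, hi = np.percentile(values, [0.1, 99.9])
    if hi <= lo:  # (near-)degenerate distribution
        return float(lo), float(values.std())
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    return float(mode), float(values.std())
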