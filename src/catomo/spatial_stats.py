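"""Spatial statistics of the granule catalog.

Three kinds of summaries are computed from detected granule centroids:

* a Gaussian k-nearest-neighbour **density field** — at each grid coordinate
  the sum of ``exp(−dist_i² / (2σ²))`` over the k = 5 nearest granule
  centroids (σ = 50 μm), the standard visualization metric for granule
  clustering; its unit is arbitrary and its values lie in (0, k];
* **ROI densities** in count/mm³ (centroid-in-mask counting), including the
  1.6 mm-wide midline band used for the dorsomedial periaqueductal gray;
* max-normalized **size histograms** of equivalent spherical diameters.

The module also carries the published per-subject reference densities for
the dmPAG and superior colliculus (count/mm³) and the dmPAG-to-colliculus
ratio, whose minimum across subjects is threefold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError
from .granule_detect import GranuleCatalog
from .volume_io import BinaryMask, Volume3D

__all__ = [
    "DensityParams",
    "DensityField",
    "density_field",
    "roi_density",
    "midline_band_roi",
    "size_histogram",
    "dmpag_to_colliculus_ratio",
    "REPORTED_CA_DENSITIES_MM3",
    "reported_density_ratios",
]

#: Published per-subject corpora amylacea densities (count/mm³) in the
#: dorsomedial periaqueductal gray and the superior colliculus of four
#: post-mortem subjects (ages 68–81 y).  Used as reference input for the
#: density-ratio analysis; subject 2 lacks a dmPAG acquisition.
REPORTED_CA_DENSITIES_MM3: dict[str, dict[str, float]] = {
    "dmpag": {"subject_1": 855.0, "subject_3": 1020.0, "subject_4": 4197.0},
    "superior_colliculus": {
        "subject_1": 150.0,
        "subject_2": 217.0,
        "subject_3": 340.0,
        "subject_4": 315.0,
    },
}


@dataclasses.dataclass
class DensityParams:
    """k-NN Gaussian density parameters: σ (μm), k, and grid spacing (μm)."""

    sigma: float = 50.0
    k_neighbors: int = 5
    grid_spacing: float = 10.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DomainError("sigma must be positive")
        if self.k_neighbors < 1:
            raise DomainError("k_neighbors must be >= 1")
        if not self.grid_spacing > 0:
            raise DomainError("grid_spacing must be positive")


@dataclasses.dataclass
class DensityField(Volume3D):
    """Scalar density values on a sampling grid (arbitrary unit, ≤ k)."""


def density_field(
    catalog: GranuleCatalog,
    geometry: Volume3D | None = None,
    params: DensityParams | None = None,
    *,
    extent_um: tuple[float, float, float] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DensityField:
    """Gaussian k-NN density of granule centroids on a coarse grid.

    The sampling grid either matches ``geometry``'s physical extent or is
    given explicitly by ``extent_um``/``origin``; spacing comes from
    ``params.grid_spacing``.  With fewer than k granules in the catalog the
    sum runs over the available ones.
    """
    params = params or DensityParams()
    pts = catalog.centroids
    if pts.shape[0] == 0:
        raise DomainError("density_field requires a non-empty catalog")
    if geometry is not None:
        origin = geometry.origin
        extent = np.array(geometry.shape, dtype=float) * geometry.voxel_size
    elif extent_um is not None:
        extent = np.asarray(extent_um, dtype=float)
    else:
        raise DomainError("either geometry or extent_um must be given")
    s = params.grid_spacing
    shape = tuple(max(int(np.floor(e / s)), 1) for e in extent)
    axes = [o + (np.arange(n) + 0.5) * s for o, n in zip(origin, shape)]
    grid = np.stack(
        [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1
    )
    k = min(params.k_neighbors, pts.shape[0])
    dist, _ = cKDTree(pts).query(grid, k=k)
    dist = np.atleast_2d(dist.reshape(len(grid), k))
    values = np.exp(-(dist**2) / (2.0 * params.sigma**2)).sum(axis=1)
    return DensityField(
        data=values.reshape(shape), voxel_size=s, origin=origin
    )


def density_at_points(
    catalog: GranuleCatalog, points_um: np.ndarray, params: DensityParams | None = None
) -> np.ndarray:
    """Density metric at arbitrary physical coordinates (same definition)."""
    params = params or DensityParams()
    pts = catalog.centroids
    if pts.shape[0] == 0:
        raise DomainError("requires a non-empty catalog")
    q = np.atleast_2d(np.asarray(points_um, dtype=float))
    k = min(params.k_neighbors, pts.shape[0])
    dist, _ = cKDTree(pts).query(q, k=k)
    dist = dist.reshape(len(q), k)
    return np.exp(-(dist**2) / (2.0 * params.sigma**2)).sum(axis=1)


def roi_density(catalog: GranuleCatalog, roi: BinaryMask) -> float:
    """Granule count per mm³ of ROI: centroid-in-mask counting.

    A granule is inside the ROI iff the voxel containing its centroid is in
    the mask; the ROI volume is the in-mask voxel count times the voxel
    volume.
    """
    n_roi = roi.n_voxels
    if n_roi == 0:
        raise DomainError("ROI is empty")
    count = 0
    shape = roi.data.shape
    for c in catalog.centroids:
        idx = np.floor(roi.um_to_index(c) + 0.5).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape) and roi.data[tuple(idx)]:
            count += 1
    volume_mm3 = n_roi * (roi.voxel_size * 1e-3) ** 3
    return count / volume_mm3


def midline_band_roi(
    tissue: BinaryMask, midline_x: float, width: float = 1600.0
) -> BinaryMask:
    """Tissue voxels within a band of the given width around a midline.

    Selects columns whose x voxel center lies in the half-open interval
    ``[midline_x − width/2, midline_x + width/2)`` (μm); the default width is
    the 1.6 mm band used for the dorsomedial periaqueductal gray.
    """
    if not width > 0:
        raise DomainError("width must be positive")
    nx = tissue.data.shape[2]
    x_centers = tissue.origin[2] + (np.arange(nx) + 0.5) * tissue.voxel_size
    in_band = (x_centers >= midline_x - width / 2.0) & (
        x_centers < midline_x + width / 2.0
    )
    data = tissue.data & in_band[None, None, :]
    if not data.any():
        warnings.warn("midline band does not intersect the tissue mask", stacklevel=2)
    return BinaryMask(data=data, voxel_size=tissue.voxel_size, origin=tissue.origin)


def size_histogram(
    catalog: GranuleCatalog, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Diameter histogram normalized by its largest bin (max height = 1).

    Returns ``(bin_edges, heights)`` with edges on multiples of
    ``bin_width`` covering the observed diameter range.
    """
    d = catalog.diameters
    if d.size == 0:
        raise DomainError("size_histogram requires a non-empty catalog")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return edges, counts / counts.max()


def dmpag_to_colliculus_ratio(d_dmpag: float, d_sc: float) -> float:
    """Ratio of dmPAG density to superior-colliculus density."""
    if d_sc <= 0:
        raise DomainError("colliculus density must be positive")
    return float(d_dmpag) / float(d_sc)


def reported_density_ratios() -> dict[str, float]:
    """Per-subject dmPAG/colliculus ratios from the reference densities."""
    dmpag = REPORTED_CA_DENSITIES_MM3["dmpag"]
    sc = REPORTED_CA_DENSITIES_MM3["superior_colliculus"]
    return {
        s: dmpag_to_colliculus_ratio(dmpag[s], sc[s]) for s in dmpag if s in sc
    }
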