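"""Synthetic phantoms with known ground truth.

The tomographic phantom reproduces the statistical structure the analysis
assumes of reconstructed phase-contrast volumes: a tissue background with a
well-defined intensity mode and SD, hyperintense quasi-spherical granules
(lognormal diameters, clipped to 2–40 μm), per-slice low-order intensity
shading, straight or single-bend tubular vessels (hypointense lumen with a
bright phase-contrast rim), and additive Gaussian noise.  Granule spheres
are antialiased by fractional boundary coverage so their voxelized volumes
are unbiased, which keeps recovery tests sharp.

Companion generators emulate the other two modalities: multi-echo
gradient-echo magnitude series with Rician noise (for R2* fitting) and flat
2D RGB "histology" images with white open lumina, dark-red blood-filled
vessels and distractor regions (for the color/area candidate rules).

Every generator is fully determined by its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import CapacityError, DomainError
from .relaxometry import EchoSeries
from .volume_io import BinaryMask, Volume3D

__all__ = [
    "PhantomSpec",
    "GranuleTruth",
    "GroundTruth",
    "make_shading",
    "generate_phantom",
    "generate_echo_series",
    "generate_histology_image",
    "generate_vessel_contact_scene",
    "match_catalog_to_truth",
]

MIN_DIAMETER_UM = 2.0
MAX_DIAMETER_UM = 40.0
MAX_PLACEMENT_ATTEMPTS = 10_000
_VOLUME_FILTER_UM3 = 365.0  # detection-stage volume cut, for truth flags


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the tomographic phantom.

    Intensities are in arbitrary units; ``granule_contrast`` and the vessel
    contrasts are multiples of ``tissue_sd``.  The default granule contrast
    of 8·SD places granule cores comfortably above the 6·SD seed threshold of
    the detector.  ``shading_coefficients`` is an optional per-slice array of
    full bivariate-quadratic coefficients (see ``preprocess.BackgroundModel``).
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0
    tissue_mode: float = 100.0
    tissue_sd: float = 5.0
    n_granules: int = 50
    diameter_log_mu: float = float(np.log(15.0))
    diameter_log_sigma: float = 0.25
    diameter_range: tuple[float, float] = (MIN_DIAMETER_UM, MAX_DIAMETER_UM)
    granule_contrast: float = 8.0
    n_vessels: int = 0
    vessel_radius_range: tuple[float, float] = (10.0, 25.0)
    vessel_rim_contrast: float = 4.0
    vessel_lumen_drop: float = 4.0
    shading_coefficients: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissue_sd > 0:
            raise DomainError("tissue_sd must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_granules < 0 or self.n_vessels < 0:
            raise DomainError("object counts must be non-negative")
        lo, hi = self.diameter_range
        if not (MIN_DIAMETER_UM <= lo < hi <= MAX_DIAMETER_UM):
            raise DomainError(
                f"diameter_range must lie within [{MIN_DIAMETER_UM}, {MAX_DIAMETER_UM}] μm"
            )


@dataclasses.dataclass
class GranuleTruth:
    """One placed granule: exact center, diameter and analytic volume."""

    center_um: tuple[float, float, float]  # (z, y, x)
    diameter_um: float
    volume_um3: float
    above_filter: bool  # true analytic volume exceeds the 365 μm³ cut


@dataclasses.dataclass
class GroundTruth:
    granules: list[GranuleTruth]
    vessel_mask: BinaryMask
    tissue_mask: BinaryMask

    @property
    def centers(self) -> np.ndarray:
        if not self.granules:
            return np.empty((0, 3))
        return np.array([g.center_um for g in self.granules])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([g.diameter_um for g in self.granules])


def make_shading(
    shape: tuple[int, int, int], amplitude: float, seed: int = 0
) -> np.ndarray:
    """Smooth per-slice quadratic shading coefficients of peak ~``amplitude``.

    Coefficients vary linearly across slices so the shading drifts slowly in
    z, as flat-field residuals do in real reconstructions.
    """
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    # unit coefficients at the first and last slice, interpolated in between
    u0, u1 = rng.uniform(-1.0, 1.0, size=(2, 6))
    w = np.linspace(0.0, 1.0, nz)[:, None]
    u = (1 - w) * u0 + w * u1  # (nz, 6)
    scale = amplitude * np.array(
        [0.0, 1.0 / nx, 1.0 / ny, 1.0 / nx**2, 1.0 / (nx * ny), 1.0 / ny**2]
    )
    return u * scale


def _sphere_coverage(
    shape: tuple[int, int, int], center_vox: np.ndarray, radius_vox: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Fractional voxel coverage of a sphere, on its bounding crop.

    Coverage ramps linearly over one voxel across the boundary, which leaves
    the summed (voxelized) volume unbiased.
    """
    lo = np.maximum(np.floor(center_vox - radius_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + radius_vox + 2).astype(int), shape)
    grids = np.meshgrid(
        *(np.arange(a, b, dtype=np.float64) for a, b in zip(lo, hi)),
        indexing="ij",
        sparse=True,
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    cov = np.clip(radius_vox - np.sqrt(d2) + 0.5, 0.0, 1.0)
    return tuple(slice(a, b) for a, b in zip(lo, hi)), cov


def _segment_distance(points, a, b):
    """Distance from broadcastable point grids to segment ab (μm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = 0.0
    else:
        t = sum((p - ai) * di for p, ai, di in zip(points, a, ab)) / denom
        t = np.clip(t, 0.0, 1.0)
    return np.sqrt(
        sum((p - (ai + t * di)) ** 2 for p, ai, di in zip(points, a, ab))
    )


def _place_center(
    rng: np.random.Generator,
    extent: np.ndarray,
    radius_um: float,
    margin_um: float,
    placed: list[tuple[np.ndarray, float]],
    min_gap_um: float,
    clearance: "callable | None" = None,
) -> np.ndarray:
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        lo = radius_um + margin_um
        hi = extent - radius_um - margin_um
        if np.any(hi <= lo):
            raise CapacityError(
                f"object of radius {radius_um:.1f} μm does not fit in extent {extent}"
            )
        c = rng.uniform(lo, hi)
        if any(
            np.linalg.norm(c - pc) < radius_um + pr + min_gap_um for pc, pr in placed
        ):
            continue
        if clearance is not None and not clearance(c, radius_um):
            continue
        return c
    raise CapacityError(
        f"placement failed after {MAX_PLACEMENT_ATTEMPTS} attempts; "
        f"{len(placed)} objects placed"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Render the tomographic phantom and its exhaustive ground truth.

    Construction order: tissue background at the mode, vessels (lumen drop +
    bright rim), antialiased granule spheres (kept clear of vessels), optional
    per-slice polynomial shading, then Gaussian noise.  Granule centers are
    pairwise separated by at least the sum of radii plus two voxels.  Identical
    specs (same seed) produce bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    h = spec.voxel_size
    extent = np.array(shape, dtype=float) * h
    vol = np.full(shape, float(spec.tissue_mode), dtype=np.float64)
    vessel_mask = np.zeros(shape, dtype=bool)
    rim_width = 2.0 * h

    # --- vessels: straight or single-bend tubes spanning the volume
    vessel_segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    if spec.n_vessels > 0:
        centers = [
            np.asarray(g, dtype=np.float64)
            for g in np.meshgrid(
                *((np.arange(n) + 0.5) * h for n in shape), indexing="ij", sparse=True
            )
        ]
        for _ in range(spec.n_vessels):
            r = rng.uniform(*spec.vessel_radius_range)
            axis = int(rng.integers(0, 3))
            lat = [ax for ax in range(3) if ax != axis]
            a = np.zeros(3)
            b = np.zeros(3)
            a[axis], b[axis] = 0.0, extent[axis]
            for ax in lat:
                a[ax] = rng.uniform(0.25, 0.75) * extent[ax]
                b[ax] = rng.uniform(0.25, 0.75) * extent[ax]
            segs = [(a, b)]
            if rng.random() < 0.5:  # single bend at the midpoint
                mid = 0.5 * (a + b)
                for ax in lat:
                    mid[ax] += rng.uniform(-0.15, 0.15) * extent[ax]
                segs = [(a, mid), (mid, b)]
            dist = np.minimum.reduce(
                [_segment_distance(centers, s0, s1) for s0, s1 in segs]
            )
            lumen_cov = np.clip((r - dist) / h + 0.5, 0.0, 1.0)
            rim_w = np.clip((dist - r) / h + 0.5, 0.0, 1.0) * np.clip(
                (r + rim_width - dist) / h + 0.5, 0.0, 1.0
            )
            vol += (
                -spec.vessel_lumen_drop * spec.tissue_sd * lumen_cov
                + spec.vessel_rim_contrast * spec.tissue_sd * rim_w
            )
            vessel_mask |= dist <= r + rim_width
            for s0, s1 in segs:
                vessel_segments.append((s0, s1, r))

    def vessel_clearance(center: np.ndarray, radius: float) -> bool:
        for s0, s1, vr in vessel_segments:
            d = _segment_distance([np.array([c]) for c in center], s0, s1)[0]
            if d < radius + vr + rim_width + 2.0 * h:
                return False
        return True

    # --- granules: antialiased solid spheres
    truths: list[GranuleTruth] = []
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_granules):
        d = float(
            np.clip(
                rng.lognormal(spec.diameter_log_mu, spec.diameter_log_sigma),
                *spec.diameter_range,
            )
        )
        radius = d / 2.0
        c = _place_center(
            rng,
            extent,
            radius,
            2.0 * h,
            placed,
            2.0 * h,
            clearance=vessel_clearance if vessel_segments else None,
        )
        placed.append((c, radius))
        slc, cov = _sphere_coverage(shape, c / h - 0.5, radius / h)
        vol[slc] += spec.granule_contrast * spec.tissue_sd * cov
        volume = np.pi / 6.0 * d**3
        truths.append(
            GranuleTruth(
                center_um=tuple(c),
                diameter_um=d,
                volume_um3=volume,
                above_filter=volume > _VOLUME_FILTER_UM3,
            )
        )

    if spec.shading_coefficients is not None:
        from .preprocess import BackgroundModel

        coeffs = np.asarray(spec.shading_coefficients, dtype=np.float64)
        if coeffs.shape != (shape[0], 6):
            raise DomainError(
                f"shading_coefficients must have shape ({shape[0]}, 6), got {coeffs.shape}"
            )
        vol += BackgroundModel(coefficients=coeffs, slice_shape=shape[1:]).evaluate()

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=shape)

    geometry = dict(voxel_size=h, origin=(0.0, 0.0, 0.0))
    truth = GroundTruth(
        granules=truths,
        vessel_mask=BinaryMask(data=vessel_mask, **geometry),
        tissue_mask=BinaryMask(data=np.ones(shape, dtype=bool), **geometry),
    )
    return Volume3D(data=vol, **geometry), truth


def generate_echo_series(
    r2star_truth: np.ndarray,
    s0: np.ndarray,
    echo_times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EchoSeries:
    """Multi-echo magnitude series s0·exp(−R2*·t) with Rician noise.

    The noise is the magnitude of complex Gaussian noise added to the
    noiseless real signal: sqrt((s + n₁)² + n₂²) with n₁, n₂ ~ N(0, σ).
    """
    r2 = np.asarray(r2star_truth, dtype=np.float64)
    s0 = np.broadcast_to(np.asarray(s0, dtype=np.float64), r2.shape)
    if np.any(r2 < 0):
        raise DomainError("R2* truth map must be non-negative")
    t = np.asarray(echo_times, dtype=np.float64)
    if t.size < 3 or not np.all(np.diff(t) > 0):
        raise DomainError("need >= 3 strictly increasing echo times")
    rng = np.random.default_rng(seed)
    echoes = np.empty((t.size,) + r2.shape)
    for i, ti in enumerate(t):
        s = s0 * np.exp(-r2 * ti)
        if noise_sd > 0:
            n1 = rng.normal(0.0, noise_sd, size=r2.shape)
            n2 = rng.normal(0.0, noise_sd, size=r2.shape)
            s = np.sqrt((s + n1) ** 2 + n2**2)
        echoes[i] = s
    return EchoSeries(magnitudes=echoes, echo_times=t)


_TISSUE_RGB = (190, 145, 165)      # eosin-like background, mean < 205, red >= 5
_LUMEN_RGB = (240, 238, 241)       # open perivascular lumen, channel mean > 205
_RBC_RGB = (2, 18, 28)             # blood-filled vessel, red channel < 5
_GRAY_RGB = (120, 110, 125)        # distractor satisfying neither color rule


def generate_histology_image(
    width: int,
    height: int,
    pixel_size: float,
    n_open_vessels: int = 0,
    n_rbc_vessels: int = 0,
    n_distractors: int = 0,
    seed: int = 0,
    open_area_range: tuple[float, float] = (6000.0, 20000.0),
    rbc_area_range: tuple[float, float] = (1500.0, 8000.0),
    distractor_area_range: tuple[float, float] = (200.0, 3000.0),
) -> tuple[np.ndarray, list[dict]]:
    """Flat-color histology phantom with circular regions and truth list.

    Open lumina are near-white disks above the 5,000 μm² rule area by
    default; blood-filled vessels are dark disks with red channel below 5;
    distractors alternate between small white disks (below the lumen area
    cut) and mid-gray disks that satisfy neither color rule.  Region areas
    are drawn uniformly from the given ranges (μm²).
    """
    if min(n_open_vessels, n_rbc_vessels, n_distractors) < 0:
        raise DomainError("object counts must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = _TISSUE_RGB
    yy, xx = np.mgrid[0:height, 0:width]
    placed: list[tuple[np.ndarray, float]] = []
    truth: list[dict] = []

    def place_disk(area_um2: float, color, cls: str) -> None:
        r_px = float(np.sqrt(area_um2 / np.pi) / pixel_size)
        if height - r_px - 2 <= r_px + 2 or width - r_px - 2 <= r_px + 2:
            raise CapacityError(
                f"disk of radius {r_px:.0f} px does not fit in {height}x{width}"
            )
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            c = rng.uniform(
                [r_px + 2, r_px + 2], [height - r_px - 2, width - r_px - 2]
            )
            if all(np.linalg.norm(c - pc) >= r_px + pr + 2 for pc, pr in placed):
                break
        else:
            raise CapacityError(f"could not place disk after {len(placed)} regions")
        placed.append((c, r_px))
        disk = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r_px**2
        img[disk] = color
        truth.append(
            {
                "class": cls,
                "center_px": (float(c[0]), float(c[1])),
                "radius_px": r_px,
                "area_um2": float(np.count_nonzero(disk)) * pixel_size**2,
            }
        )

    for _ in range(n_open_vessels):
        place_disk(rng.uniform(*open_area_range), _LUMEN_RGB, "open_lumen")
    for _ in range(n_rbc_vessels):
        place_disk(rng.uniform(*rbc_area_range), _RBC_RGB, "rbc_vessel")
    for i in range(n_distractors):
        area = rng.uniform(*distractor_area_range)
        if i % 2 == 0:
            place_disk(area, _GRAY_RGB, "distractor")
        else:  # small bright disk, below the open-lumen area rule
            place_disk(min(area, 3000.0), _LUMEN_RGB, "distractor")
    return img, truth


@dataclasses.dataclass
class ContactScene:
    """A rendered tube-plus-granules scene with constructed contact truth."""

    volume: Volume3D
    labels: np.ndarray  # int32 granule labels
    vessel_mask: BinaryMask
    touching: list[bool]  # per label (1-based order), constructed contact state


def generate_vessel_contact_scene(
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 2.0,
    n_granules: int = 100,
    n_touching: int = 7,
    granule_diameter_range: tuple[float, float] = (10.0, 16.0),
    tube_radius_um: float = 20.0,
    tissue_mode: float = 100.0,
    tissue_sd: float = 5.0,
    granule_contrast: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ContactScene:
    """Labeled granules around a straight tube, with known contact truth.

    Exactly ``n_touching`` granules are placed so their voxelized sphere
    overlaps the tube mask by at least one voxel; the rest keep a safety
    margin.  The scene is also rendered as an intensity volume (tube lumen
    drop, bright rim, hyperintense granules, optional noise) so that
    segmentation can be exercised with and without granule inpainting.  The
    constructed contact state is the oracle for the CA–vessel contact
    fraction.
    """
    if n_touching > n_granules:
        raise DomainError("n_touching cannot exceed n_granules")
    rng = np.random.default_rng(seed)
    h = voxel_size
    extent = np.array(shape, dtype=float) * h
    rim = 2.0 * h
    r_out = tube_radius_um + rim  # tube mask includes the rim shell
    axis_point = np.array([0.0, extent[1] / 2.0, extent[2] / 2.0])

    centers = [
        np.asarray(g, dtype=np.float64)
        for g in np.meshgrid(
            *((np.arange(n) + 0.5) * h for n in shape), indexing="ij", sparse=True
        )
    ]
    radial = np.sqrt(
        (centers[1] - axis_point[1]) ** 2 + (centers[2] - axis_point[2]) ** 2
    ) + 0.0 * centers[0]
    vessel = radial <= r_out

    vol = np.full(shape, float(tissue_mode), dtype=np.float64)
    lumen_cov = np.clip((tube_radius_um - radial) / h + 0.5, 0.0, 1.0)
    rim_w = np.clip((radial - tube_radius_um) / h + 0.5, 0.0, 1.0) * np.clip(
        (r_out - radial) / h + 0.5, 0.0, 1.0
    )
    vol += tissue_sd * (4.0 * rim_w - 4.0 * lumen_cov)

    labels = np.zeros(shape, dtype=np.int32)
    placed: list[tuple[np.ndarray, float]] = []
    touching_flags: list[bool] = []
    label = 0
    for i in range(n_granules):
        d = rng.uniform(*granule_diameter_range)
        r = d / 2.0
        touch = i < n_touching
        rad_lo, rad_hi = r_out + r + 4.0 * h, extent[1] / 2.0 - r - 2 * h
        if rad_hi <= rad_lo:
            raise CapacityError(
                f"no room for granules of radius {r:.1f} μm around a tube of "
                f"outer radius {r_out:.1f} μm in extent {extent[1]:.0f} μm"
            )
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            if touch:
                rad = r_out + r - 1.5 * h  # guarantees >= 1 overlap voxel
            else:
                rad = rng.uniform(rad_lo, rad_hi)
            theta = rng.uniform(0, 2 * np.pi)
            c = np.array(
                [
                    rng.uniform(r + 2 * h, extent[0] - r - 2 * h),
                    axis_point[1] + rad * np.sin(theta),
                    axis_point[2] + rad * np.cos(theta),
                ]
            )
            if np.any(c < r + h) or np.any(c > extent - r - h):
                continue
            if all(np.linalg.norm(c - pc) >= r + pr + 2 * h for pc, pr in placed):
                break
        else:
            raise CapacityError(f"placed {label} of {n_granules} granules")
        placed.append((c, r))
        label += 1
        slc, cov = _sphere_coverage(shape, c / h - 0.5, r / h)
        labels[slc][cov >= 0.5] = label
        vol[slc] += granule_contrast * tissue_sd * cov
        touching_flags.append(touch)

    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=shape)
    geometry = dict(voxel_size=h, origin=(0.0, 0.0, 0.0))
    return ContactScene(
        volume=Volume3D(data=vol, **geometry),
        labels=labels,
        vessel_mask=BinaryMask(data=vessel, **geometry),
        touching=touching_flags,
    )


def match_catalog_to_truth(
    catalog, truth: GroundTruth, *, distance_factor: float = 1.0
) -> dict:
    """Greedy nearest match of detected granules to ground truth.

    A truth granule counts as recovered when a detected centroid lies within
    ``distance_factor`` times its diameter; each detection matches at most
    one truth object.  Returns sensitivity over above-filter truth granules,
    the false-positive count, and paired (true, detected) diameters.
    """
    from scipy.spatial import cKDTree

    det = catalog.centroids
    det_d = catalog.diameters
    eligible = [g for g in truth.granules if g.above_filter]
    if det.shape[0] == 0:
        return {
            "n_truth": len(eligible),
            "n_detected": 0,
            "n_matched": 0,
            "n_false_positives": 0,
            "sensitivity": 0.0 if eligible else 1.0,
            "pairs": np.empty((0, 2)),
        }
    tree = cKDTree(det)
    used: set[int] = set()
    pairs = []
    for g in sorted(eligible, key=lambda g: -g.diameter_um):
        dist, j = tree.query(np.asarray(g.center_um))
        if j in used or dist > distance_factor * g.diameter_um:
            continue
        used.add(int(j))
        pairs.append((g.diameter_um, det_d[int(j)]))
    n_matched = len(pairs)
    return {
        "n_truth": len(eligible),
        "n_detected": int(det.shape[0]),
        "n_matched": n_matched,
        "n_false_positives": int(det.shape[0]) - n_matched,
        "sensitivity": n_matched / len(eligible) if eligible else 1.0,
        "pairs": np.asarray(pairs) if pairs else np.empty((0, 2)),
    }
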