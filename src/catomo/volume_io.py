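"""Volume containers and file I/O.

All tomographic data are carried as :class:`Volume3D`: a 3D scalar grid with an
isotropic physical voxel size in micrometres and axes ordered ``(z, y, x)``
with ``z`` the slice axis of a TIFF stack.  The physical coordinate of the
center of voxel ``(i, j, k)`` is ``origin + (index + 0.5) * voxel_size`` per
axis, so centroids and distances everywhere in the package are in μm.

Supported formats: multi-page grayscale TIFF stacks (voxel size supplied by
the caller) and NIfTI ``.nii``/``.nii.gz`` (voxel size persisted in the
affine, in μm, with ``xyzt_units`` set to micron).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import DomainError, FormatError, GeometryError

__all__ = [
    "Volume3D",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_rgb_image",
    "write_rgb_image",
    "max_intensity_projection",
    "same_geometry",
]


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar intensity grid with isotropic voxel geometry.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.
    voxel_size
        Edge length of a voxel in μm; must be positive.
    origin
        Physical offset of the corner of voxel ``(0, 0, 0)`` in μm.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise GeometryError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_um(self, index) -> np.ndarray:
        """Physical coordinates (μm) of voxel centers for (z, y, x) indices."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * self.voxel_size

    def um_to_index(self, coords) -> np.ndarray:
        """Inverse of :meth:`index_to_um`; returns fractional (z, y, x) indices."""
        c = np.asarray(coords, dtype=float)
        return (c - np.asarray(self.origin)) / self.voxel_size - 0.5


@dataclasses.dataclass
class BinaryMask(Volume3D):
    """A boolean annotation grid sharing :class:`Volume3D` geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_um3(self) -> float:
        return self.n_voxels * self.voxel_size**3


def same_geometry(a: Volume3D, b: Volume3D, *, rtol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.isclose(a.voxel_size, b.voxel_size, rtol=rtol)
        and np.allclose(a.origin, b.origin, rtol=rtol, atol=1e-9)
    )


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(
    path,
    voxel_size: float | None = None,
    *,
    force_voxel_size: bool = False,
    mask: bool = False,
) -> Volume3D:
    """Read a TIFF stack or NIfTI volume.

    For NIfTI the voxel size stored in the header (μm) takes precedence over
    the ``voxel_size`` argument unless ``force_voxel_size`` is set.  TIFF does
    not carry the spacing, so ``voxel_size`` is required.  ``mask=True``
    returns a :class:`BinaryMask` instead (data cast to bool).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        try:
            img = nib.load(path)
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # pragma: no cover - nibabel error classes vary
            raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise GeometryError(
                f"anisotropic NIfTI spacing {tuple(zooms)}; the pipeline assumes "
                "isotropic voxels"
            )
        header_vs = float(zooms[0])
        if force_voxel_size:
            if voxel_size is None:
                raise DomainError("force_voxel_size requires an explicit voxel_size")
            vs = float(voxel_size)
        else:
            vs = header_vs
        if data.ndim != 3:
            raise GeometryError(f"expected 3D NIfTI data, got ndim={data.ndim}")
        grid = np.ascontiguousarray(data.transpose(2, 1, 0))  # (x,y,z) -> (z,y,x)
    else:
        import tifffile

        try:
            grid = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"could not read TIFF stack {path}: {exc}") from exc
        if grid.ndim == 2:
            grid = grid[None]
        if grid.ndim != 3:
            raise GeometryError(f"expected a grayscale stack, got shape {grid.shape}")
        if voxel_size is None:
            raise DomainError("TIFF stacks carry no spacing; voxel_size is required")
        vs = float(voxel_size)
    cls = BinaryMask if mask else Volume3D
    return cls(data=grid, voxel_size=vs)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as TIFF or NIfTI, chosen by the file suffix.

    Integer data round-trip bit-identically.  NIfTI records the voxel size
    (μm) in the affine; TIFF does not support it and relies on the caller.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if _is_nifti(path):
        import nibabel as nib

        if data.dtype in (np.int64, np.uint64):
            data = data.astype(np.int32)
        affine = np.diag([vol.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), affine)
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, path)
    else:
        import tifffile

        tifffile.imwrite(path, data)


def read_rgb_image(path) -> np.ndarray:
    """Read a 2D RGB image (H, W, 3) uint8; alpha channels are dropped."""
    import imageio.v3 as iio

    try:
        img = np.asarray(iio.imread(Path(path)))
    except Exception as exc:
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if img.ndim != 3 or img.shape[2] < 3:
        raise FormatError(f"expected an RGB image, got shape {img.shape}")
    return img[..., :3]


def write_rgb_image(img: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def max_intensity_projection(
    vol: Volume3D, axis: int = 0, *, thickness: float, start: float
) -> np.ndarray:
    """Maximum intensity projection over a physical slab.

    The slab ``[start, start + thickness)`` is expressed in μm along the given
    axis and combines ``ceil(thickness / voxel_size)`` slices, emulating the
    thick-slab projections used to compare tomography with histology sections.
    """
    if thickness < vol.voxel_size:
        raise DomainError(
            f"thickness {thickness} μm is below the voxel size {vol.voxel_size} μm"
        )
    n = vol.shape[axis]
    o = vol.origin[axis]
    i0 = int(np.floor((start - o) / vol.voxel_size))
    n_slices = int(np.ceil(thickness / vol.voxel_size))
    i1 = i0 + n_slices
    if i1 <= 0 or i0 >= n:
        raise DomainError(
            f"slab [{start}, {start + thickness}) μm lies outside the volume"
        )
    i0, i1 = max(i0, 0), min(i1, n)
    sl = [slice(None)] * 3
    sl[axis] = slice(i0, i1)
    return np.max(vol.data[tuple(sl)], axis=axis)
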