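"""Grid-aware 3D volume types, NIfTI I/O, resampling and warping.

Conventions
-----------
* Arrays are indexed ``[ix, iy, iz]`` with ``z`` the superior-inferior axis.
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (mm). Grids are axis-aligned: oblique input
  affines are rejected rather than silently resliced.
* Displacement fields use the pull-back (resampling) convention: the warped
  image at position ``p`` samples the source at ``p + u(p)``, with ``u`` in mm
  along the physical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError, GridMismatchError

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_displacement",
    "write_displacement",
    "resample",
    "warp",
    "warp_mask",
    "overlapping_z_range",
]

_OBLIQUE_TOL = 1e-3


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape/spacing/origin must be length-3")
        if any(s < 2 for s in shape):
            raise ValueError(f"grid shape must be >= 2 per axis, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical distance between first and last sample per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinate arrays (mm), each of the grid's full shape."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def _check_same_grid(a, b, what: str = "operands"):
    if not a.grid.matches(b.grid):
        raise GridMismatchError(f"{what} must share a grid: {a.grid} vs {b.grid}")


@dataclass
class ScalarVolume:
    """A 3D intensity volume (HU-like units) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape != self.grid.shape:
            raise FormatError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """A boolean volume (body / lungs / GTV contours) on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or self.values.shape != self.grid.shape:
            raise FormatError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * float(np.prod(self.grid.spacing)) / 1000.0


@dataclass
class DisplacementField:
    """Per-voxel displacement u (mm, pull-back): warp samples source at p + u(p)."""

    grid: VolumeGrid
    vectors: np.ndarray  # (*grid.shape, 3)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        expected = self.grid.shape + (3,)
        if self.vectors.shape != expected:
            raise FormatError(
                f"vector shape {self.vectors.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise FormatError("displacement field contains non-finite values")

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors**2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape) -> VolumeGrid:
    lin = affine[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    # reject oblique orientations: off-diagonal direction cosines must vanish
    cosines = lin / spacing[np.newaxis, :]
    if not np.allclose(np.abs(cosines), np.eye(3), atol=_OBLIQUE_TOL):
        raise FormatError("oblique affine: direction cosines are not axis-aligned")
    return VolumeGrid(tuple(shape), tuple(spacing), tuple(affine[:3, 3]))


def _load_canonical(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise OSError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    return nib.as_closest_canonical(img)


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI volume; spacing/origin taken from the affine."""
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64))


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.grid.affine())
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.grid, vol.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def read_displacement(path) -> DisplacementField:
    """Read a 3-component vector NIfTI (stored as a 4D x,y,z,3 volume)."""
    img = _load_canonical(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (t=1)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"expected a 3-component vector field, got {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape[:3])
    return DisplacementField(grid, data)


def write_displacement(dvf: DisplacementField, path) -> None:
    img = nib.Nifti1Image(dvf.vectors.astype(np.float32), dvf.grid.affine())
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling and warping

_ORDER = {"linear": 1, "nearest": 0}


def resample(
    volume: ScalarVolume,
    target_spacing,
    interpolation: str = "linear",
) -> ScalarVolume:
    """Resample onto a grid with the given spacing, preserving physical extent.

    The output keeps the input origin; the number of samples per axis is the
    largest count whose span fits inside the input span (at least 2).
    """
    target = tuple(float(s) for s in np.atleast_1d(target_spacing).repeat(
        3 if np.ndim(target_spacing) == 0 else 1))
    if len(target) != 3:
        raise ValueError("target_spacing must be a scalar or length-3")
    if any(s <= 0 for s in target):
        raise ValueError(f"target_spacing must be positive, got {target}")
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    old = volume.grid
    new_shape = tuple(
        max(2, int(np.floor(ext / t + 1e-9)) + 1)
        for ext, t in zip(old.extent_mm, target)
    )
    # sample positions of the new grid, in old-grid index units
    coords = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, old.spacing)],
        indexing="ij",
    )
    out = map_coordinates(
        volume.values, np.stack(coords), order=_ORDER[interpolation], mode="nearest"
    )
    return ScalarVolume(VolumeGrid(new_shape, target, old.origin), out)


def _sample_coords(grid: VolumeGrid, vectors: np.ndarray) -> np.ndarray:
    """Index-space sampling coordinates for pull-back warping: idx + u/spacing."""
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid.shape],
                      indexing="ij")
    return np.stack(
        [idx[a] + vectors[..., a] / grid.spacing[a] for a in range(3)]
    )


def warp(
    volume: ScalarVolume,
    dvf: DisplacementField,
    interpolation: str = "linear",
    boundary: str = "replicate",
) -> ScalarVolume:
    """Apply a pull-back displacement: output(p) = input(p + u(p))."""
    _check_same_grid(volume, dvf, "volume and displacement field")
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if boundary != "replicate":
        raise ValueError(f"unsupported boundary rule {boundary!r}")
    if not dvf.vectors.any():
        return volume.copy()  # identity deformation, bit-exact
    coords = _sample_coords(volume.grid, dvf.vectors)
    out = map_coordinates(
        volume.values, coords, order=_ORDER[interpolation], mode="nearest"
    )
    return ScalarVolume(volume.grid, out)


def warp_mask(mask: BinaryMask, dvf: DisplacementField) -> BinaryMask:
    """Warp a binary mask (nearest-neighbor sampling)."""
    _check_same_grid(mask, dvf, "mask and displacement field")
    if not dvf.vectors.any():
        return BinaryMask(mask.grid, mask.values.copy())
    coords = _sample_coords(mask.grid, dvf.vectors)
    out = map_coordinates(mask.values.astype(np.uint8), coords, order=0,
                          mode="nearest")
    return BinaryMask(mask.grid, out > 0)


def overlapping_z_range(maskA: BinaryMask, maskB: BinaryMask):
    """Inclusive z-slice interval where both masks have nonempty slices.

    Each mask contributes its ``[first, last]`` nonempty-slice interval; the
    result is the intersection, or ``None`` when it is empty. Masks must share
    the x,y grid; z extents may differ.
    """
    if maskA.grid.shape[:2] != maskB.grid.shape[:2] or not np.allclose(
        maskA.grid.spacing[:2], maskB.grid.spacing[:2]
    ):
        raise GridMismatchError("masks must share the x,y grid")

    def span(mask):
        nonempty = np.flatnonzero(mask.values.any(axis=(0, 1)))
        if nonempty.size == 0:
            return None
        return int(nonempty[0]), int(nonempty[-1])

    sa, sb = span(maskA), span(maskB)
    if sa is None or sb is None:
        return None
    lo, hi = max(sa[0], sb[0]), min(sa[1], sb[1])
    return (lo, hi) if lo <= hi else None
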