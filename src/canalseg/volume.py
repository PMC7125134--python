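"""Volume containers, NIfTI/NRRD I/O and the three-step grey-value standardisation.

CBCT volumes are carried as :class:`Volume`: a 3D grid of grey values on an
isotropic voxel lattice. Grey values are on the (approximate) Hounsfield-unit
scale before preprocessing and dimensionless in [0, 1] afterwards. Binary
canal annotations are carried as :class:`VoxelMask` on the same lattice.

The standardisation pipeline is ``resample_isotropic`` (to a common voxel
spacing, trilinear), ``clip_hu`` (to the valid HU range [-1000, 3095]) and
``normalize`` (fixed affine map of the clip range onto [0, 1]).

Conventions: grids are indexed 0-based in (x, y, z) order; the physical
position of voxel ``i`` is ``origin + i * spacing`` (voxel-centre convention).
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import nibabel as nib
from scipy import ndimage

HU_MIN = -1000.0
HU_MAX = 3095.0
_HU_RANGE = HU_MAX - HU_MIN

#: smallest voxel spacing (mm) accepted by the resampler; below this a
#: mistyped target would allocate an absurd grid.
MIN_SPACING_MM = 0.05

_ISO_RTOL = 1e-4  # relative tolerance when checking header isotropy


@dataclasses.dataclass
class Volume:
    """A 3D grey-value volume on an isotropic voxel grid.

    Parameters
    ----------
    grid :
        3D array of grey values, indexed (x, y, z).
    spacing :
        Isotropic voxel edge length in mm (single scalar, > 0).
    origin :
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: float
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.grid.ndim}")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (possibly fractional) to physical mm coordinates."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def copy_with(self, grid: np.ndarray) -> "Volume":
        return Volume(grid=grid, spacing=self.spacing, origin=self.origin.copy())


@dataclasses.dataclass
class VoxelMask:
    """A binary annotation aligned to a :class:`Volume` grid."""

    grid: np.ndarray
    spacing: float
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={grid.ndim}")
        vals = np.unique(grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be strictly binary (0/1)")
        self.grid = grid.astype(np.uint8)
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_to_mm(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def count(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# standardisation steps
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; output shapes must use half-away-from-zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_isotropic(volume: Volume, target_spacing: float) -> Volume:
    """Resample a volume to ``target_spacing`` with trilinear interpolation.

    The output shape per axis is ``round(shape * spacing / target)`` (ties
    away from zero), which preserves the physical extent to within one voxel.
    The origin (voxel-centre of index 0) is kept.
    """
    target_spacing = float(target_spacing)
    if target_spacing < MIN_SPACING_MM:
        raise ValueError(
            f"target spacing {target_spacing} mm is below the "
            f"{MIN_SPACING_MM} mm safety floor"
        )
    if volume.spacing <= 0:
        raise ValueError("input spacing must be > 0")
    if abs(volume.spacing - target_spacing) < 1e-9:
        return volume.copy_with(volume.grid.copy())

    in_shape = np.array(volume.shape, dtype=float)
    scale = volume.spacing / target_spacing
    out_shape = _round_half_away(in_shape * scale).astype(int)
    out_shape = np.maximum(out_shape, 1)

    # voxel-centre mapping: output index i sits at physical i*target, i.e.
    # input index i*target/spacing
    coords = np.meshgrid(
        *[np.arange(n) * (target_spacing / volume.spacing) for n in out_shape],
        indexing="ij",
    )
    grid = ndimage.map_coordinates(
        volume.grid.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )
    return Volume(grid=grid, spacing=target_spacing, origin=volume.origin.copy())


def resample_mask(mask: VoxelMask, target_spacing: float) -> VoxelMask:
    """Resample a binary mask with nearest-neighbour interpolation.

    Labels must stay strictly binary, so the trilinear scheme used for grey
    values is not applicable.
    """
    target_spacing = float(target_spacing)
    if target_spacing < MIN_SPACING_MM:
        raise ValueError(
            f"target spacing {target_spacing} mm is below the "
            f"{MIN_SPACING_MM} mm safety floor"
        )
    if abs(mask.spacing - target_spacing) < 1e-9:
        return VoxelMask(mask.grid.copy(), mask.spacing, mask.origin.copy())
    in_shape = np.array(mask.shape, dtype=float)
    out_shape = _round_half_away(in_shape * mask.spacing / target_spacing).astype(int)
    out_shape = np.maximum(out_shape, 1)
    coords = np.meshgrid(
        *[np.arange(n) * (target_spacing / mask.spacing) for n in out_shape],
        indexing="ij",
    )
    grid = ndimage.map_coordinates(
        mask.grid, np.stack(coords), order=0, mode="nearest"
    )
    return VoxelMask(grid=grid, spacing=target_spacing, origin=mask.origin.copy())


def clip_hu(volume: Volume) -> Volume:
    """Clip grey values to the valid Hounsfield range [-1000, 3095]."""
    return volume.copy_with(np.clip(volume.grid, HU_MIN, HU_MAX))


def normalize(volume: Volume) -> Volume:
    """Map the clipped HU range [-1000, 3095] affinely onto [0, 1].

    The map is fixed (``v -> (v + 1000) / 4095``) rather than per-volume
    min-max, so identical tissue gets identical normalised intensity across
    scans. Values outside the clip range are rejected: run :func:`clip_hu`
    first.
    """
    g = volume.grid
    if g.min() < HU_MIN - 1e-9 or g.max() > HU_MAX + 1e-9:
        raise ValueError(
            "grey values outside the clip range [-1000, 3095]; apply clip_hu first"
        )
    return volume.copy_with((g - HU_MIN) / _HU_RANGE)


def preprocess(volume: Volume, target_spacing: float = 0.4) -> Volume:
    """Apply the full standardisation: resample, clip, normalise."""
    return normalize(clip_hu(resample_isotropic(volume, target_spacing)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _check_isotropic(zooms, path) -> float:
    zooms = np.asarray(zooms[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=_ISO_RTOL, atol=0):
        raise ValueError(
            f"{path}: anisotropic voxel spacing {tuple(zooms)}; only isotropic "
            "volumes are supported"
        )
    return float(zooms[0])


def _read_nifti(path: pathlib.Path):
    img = nib.load(str(path))
    spacing = _check_isotropic(img.header.get_zooms(), path)
    grid = np.asanyarray(img.dataobj)
    if grid.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {grid.shape}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return grid, spacing, origin


def _read_nrrd(path: pathlib.Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = _check_isotropic(img.GetSpacing(), path)
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return grid, spacing, origin


def read_volume(path) -> Volume:
    """Read a volume from NIfTI-1 (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        grid, spacing, origin = _read_nifti(path)
    elif name.endswith(".nrrd"):
        grid, spacing, origin = _read_nrrd(path)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    return Volume(grid=grid, spacing=spacing, origin=origin)


def read_mask(path) -> VoxelMask:
    """Read a binary mask; values are validated as strictly binary."""
    vol = read_volume(path)
    return VoxelMask(grid=vol.grid, spacing=vol.spacing, origin=vol.origin)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1; grid values are preserved bitwise."""
    path = pathlib.Path(path)
    affine = np.diag([volume.spacing] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.grid, affine)
    img.header.set_zooms((volume.spacing,) * 3)
    nib.save(img, str(path))


def write_mask(mask: VoxelMask, path) -> None:
    """Write a mask as unsigned 8-bit NIfTI-1."""
    write_volume(
        Volume(mask.grid.astype(np.uint8), mask.spacing, mask.origin), path
    )
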