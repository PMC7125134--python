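"""Training patch extraction on a stride grid, canal filtering, flip augmentation.

Whole CBCT volumes are too large to train on directly, so 32^3 patches are
taken on a stride-22 grid. To reduce the extreme class imbalance, patches
without a single canal voxel are discarded. The stride grid alone need not
reach the last voxels of an axis, so a snapped final position at
``shape - 32`` is added per axis; with stride 22 < 32 this guarantees every
canal voxel appears in at least one retained patch.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .volume import Volume, VoxelMask

PATCH_SIZE = 32
STRIDE = 22


@dataclasses.dataclass
class Patch:
    """A 32^3 image/label block cut from a parent volume."""

    image: np.ndarray
    label: np.ndarray
    origin_index: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image and label shapes must match")
        if any(s != PATCH_SIZE for s in self.image.shape):
            raise ValueError(
                f"expected {PATCH_SIZE}^3 patches, got {self.image.shape}"
            )


def grid_positions(
    volume_shape,
    patch_size: int = PATCH_SIZE,
    stride: int = STRIDE,
) -> list[tuple[int, int, int]]:
    """Patch corner indices on the stride grid with boundary snap.

    Per axis: ``{0, stride, 2*stride, ...}`` up to ``shape - patch_size``,
    plus a final snapped position ``shape - patch_size`` if the grid does
    not land on it; the result is the Cartesian product over axes.
    """
    per_axis = []
    for n in volume_shape:
        if n < patch_size:
            raise ValueError(
                f"axis of length {n} is smaller than the patch size "
                f"{patch_size}; pad the volume first"
            )
        positions = list(range(0, n - patch_size + 1, stride))
        if positions[-1] != n - patch_size:
            positions.append(n - patch_size)
        per_axis.append(positions)
    return list(itertools.product(*per_axis))


def extract_training_patches(
    volume: Volume,
    mask: VoxelMask,
    patch_size: int = PATCH_SIZE,
    stride: int = STRIDE,
) -> list[Patch]:
    """Cut grid patches and keep only those containing canal voxels."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask {mask.shape}"
        )
    img = volume.grid
    lab = mask.grid
    out = []
    for pos in grid_positions(volume.shape, patch_size, stride):
        sl = tuple(slice(p, p + patch_size) for p in pos)
        label = lab[sl]
        if label.any():
            out.append(
                Patch(
                    image=np.ascontiguousarray(img[sl], dtype=np.float32),
                    label=np.ascontiguousarray(label, dtype=np.uint8),
                    origin_index=pos,
                )
            )
    return out


def augment_flip(patch: Patch, rng: np.random.Generator) -> Patch:
    """Reverse each spatial axis independently with probability 0.5.

    Image and label are flipped identically, so the patch stays a valid
    training pair.
    """
    flips = rng.random(3) < 0.5
    axes = tuple(int(a) for a in np.nonzero(flips)[0])
    if not axes:
        return patch
    return Patch(
        image=np.flip(patch.image, axis=axes).copy(),
        label=np.flip(patch.label, axis=axes).copy(),
        origin_index=patch.origin_index,
    )
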