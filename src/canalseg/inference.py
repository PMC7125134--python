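"""Whole-volume inference and connected-component post-processing.

The network is applied to overlapping 32^3 tiles on the training stride
grid (with boundary snap); each voxel's probability is the mean over all
tiles covering it. The binarised map typically contains spurious small
structures near the canal, so only the ``n_canals`` largest 26-connected
components are kept as the predicted canals — the number of canals is known
per volume. ``split_canals`` then separates them, ordered along the
left-right axis, for per-canal evaluation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .model import CanalNet
from .patches import PATCH_SIZE, STRIDE, grid_positions
from .volume import Volume, VoxelMask

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class ProbabilityVolume:
    """Per-voxel canal probability aligned to the source volume grid."""

    grid: np.ndarray
    spacing: float
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("probability grid must be 3D")
        if self.grid.min() < -1e-6 or self.grid.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)


def predict_volume(
    model: CanalNet,
    volume: Volume,
    tile: int = PATCH_SIZE,
    overlap_stride: int = STRIDE,
    batch_tiles: int = 8,
) -> ProbabilityVolume:
    """Tiled sliding-window inference with mean fusion of overlaps."""
    div = 2**model.config.n_levels
    if tile % div:
        raise ValueError(f"tile {tile} not divisible by 2^{model.config.n_levels}")
    if any(s < tile for s in volume.shape):
        raise ValueError(
            f"volume shape {volume.shape} smaller than the {tile} tile; "
            "pad the volume first"
        )
    g = volume.grid
    if g.min() < -1e-6 or g.max() > 1 + 1e-6:
        raise ValueError("volume must be preprocessed to [0, 1] before inference")
    positions = grid_positions(volume.shape, tile, overlap_stride)
    acc = np.zeros(volume.shape, dtype=np.float64)
    cnt = np.zeros(volume.shape, dtype=np.int32)
    for start in range(0, len(positions), batch_tiles):
        chunk = positions[start : start + batch_tiles]
        x = np.stack(
            [
                g[p[0] : p[0] + tile, p[1] : p[1] + tile, p[2] : p[2] + tile]
                for p in chunk
            ]
        ).astype(np.float32)[:, None]
        probs = model.forward(x, training=False)[:, 0]
        for b, p in enumerate(chunk):
            sl = tuple(slice(q, q + tile) for q in p)
            acc[sl] += probs[b]
            cnt[sl] += 1
    return ProbabilityVolume(
        (acc / cnt).astype(np.float32), volume.spacing, volume.origin.copy()
    )


def binarize(probs: ProbabilityVolume, threshold: float = 0.5) -> VoxelMask:
    """Threshold the probability map; strictly greater than ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return VoxelMask(
        (probs.grid > threshold).astype(np.uint8), probs.spacing, probs.origin
    )


def keep_largest_components(
    mask: VoxelMask, n_canals: int
) -> tuple[VoxelMask, bool]:
    """Keep the ``n_canals`` largest 26-connected components.

    Ties in component size break deterministically towards the component
    containing the lowest linear voxel index. Returns ``(mask, warning)``;
    the warning flag is set when the input mask is empty (segmentation
    failure) — fewer-than-requested components is not a failure.
    """
    if n_canals < 1:
        raise ValueError("n_canals must be >= 1")
    labels, n_comp = ndimage.label(mask.grid, structure=_CONN26)
    if n_comp == 0:
        return VoxelMask(
            np.zeros_like(mask.grid), mask.spacing, mask.origin.copy()
        ), True
    flat = labels.ravel()
    counts = np.bincount(flat)[1:]  # component k has count counts[k-1]
    first_idx = np.full(n_comp, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence per label (nz is ascending)
    seen = flat[nz]
    uniq, first_pos = np.unique(seen, return_index=True)
    first_idx[uniq - 1] = nz[first_pos]
    order = sorted(range(n_comp), key=lambda k: (-counts[k], first_idx[k]))
    keep = [k + 1 for k in order[:n_canals]]
    out = np.isin(labels, keep).astype(np.uint8)
    return VoxelMask(out, mask.spacing, mask.origin.copy()), False


def split_canals(
    filtered_mask: VoxelMask, lr_axis: int = 0
) -> list[VoxelMask]:
    """Split a post-processed mask into per-canal masks.

    Components are ordered by centroid along ``lr_axis`` (lower coordinate
    first), so predicted canals can be paired with ground-truth sides.
    """
    labels, n_comp = ndimage.label(filtered_mask.grid, structure=_CONN26)
    if n_comp > 2:
        raise ValueError(
            f"{n_comp} components after post-processing; "
            "keep_largest_components must run first"
        )
    centroids = ndimage.center_of_mass(
        filtered_mask.grid, labels, range(1, n_comp + 1)
    )
    order = np.argsort([c[lr_axis] for c in centroids], kind="stable")
    return [
        VoxelMask(
            (labels == k + 1).astype(np.uint8),
            filtered_mask.spacing,
            filtered_mask.origin.copy(),
        )
        for k in order
    ]
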