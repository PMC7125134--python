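"""Coarse canal annotation: control points -> interpolated path -> 3.0 mm tube.

This mirrors the clinical annotation workflow: a reader places a handful of
control points (about 10 per canal) along the canal, software interpolates a
smooth pathway through them, the pathway is expanded to a tube of fixed
3.0 mm diameter and the tube is discretised onto the image grid. The result
is a systematically noisy training label — sparse control points, the fixed
diameter and the discretisation all distort the true canal, which is the
label-noise regime the segmentation network is trained under.

``perturb_annotation`` synthesises such annotations from an exact phantom
centerline, for controlled label-noise experiments.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .curves import CurveLine
from .volume import Volume, VoxelMask

#: clinical tube diameter (mm) used for coarse canal annotations
DEFAULT_TUBE_DIAMETER_MM = 3.0


@dataclasses.dataclass
class ControlPointPath:
    """Ordered control points (mm) placed along one canal."""

    points: np.ndarray  # (N, 3) mm
    side: str = "unspecified"  # left / right / unspecified

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected (N, 3) control points, got {pts.shape}")
        if len(pts) < 2:
            raise ValueError("need at least 2 control points")
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive control points must be distinct")
        self.points = pts


def fit_path_spline(path: ControlPointPath):
    """Natural cubic spline through the control points.

    Returns ``(spline, knot_params)``: the spline is parametrised by
    cumulative chord length and passes exactly through every control point
    at the returned parameters. With 2 or 3 points the natural spline
    degenerates gracefully (2 points: a straight segment).
    """
    pts = path.points
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
    return spline, chord


def interpolate_path(path: ControlPointPath, step: float) -> CurveLine:
    """Interpolate the canal pathway through the control points.

    A natural cubic spline (C2 between knots) is fit through the points in
    order and resampled to a uniform arc-length step of at most ``step`` mm.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    spline, chord = fit_path_spline(path)
    # dense evaluation before arc-length resampling bounds the chord/arc gap
    n_dense = max(4 * len(path.points), int(np.ceil(chord[-1] / (step / 4))) + 1)
    dense = spline(np.linspace(0.0, chord[-1], n_dense))
    curve = CurveLine(_dedupe_rows(dense))
    return curve.resample_step(step)


def _dedupe_rows(pts: np.ndarray) -> np.ndarray:
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], gaps > 0])
    return pts[keep]


def tube_mask(
    curve: CurveLine,
    diameter: float,
    ref_volume: Volume,
    _dense_divisor: float = 4.0,
) -> VoxelMask:
    """Expand a pathway to a tube of ``diameter`` mm discretised on the grid.

    The mask is the set of voxel centres within ``diameter / 2`` of the
    densely resampled curve (distance-to-polyline with half-ball end caps).
    The dense resampling step is ``spacing / 4``, keeping the rasterisation
    error well below half a voxel.
    """
    if diameter <= 0:
        raise ValueError("tube diameter must be > 0")
    spacing = ref_volume.spacing
    lo = ref_volume.origin
    hi = ref_volume.origin + (np.array(ref_volume.shape) - 1) * spacing
    below = curve.points < lo - 1e-9
    above = curve.points > hi + 1e-9
    if below.any() or above.any():
        bad = np.argwhere(below.any(axis=1) | above.any(axis=1)).ravel()
        raise ValueError(
            f"curve leaves the volume extent at point indices {bad[:5].tolist()}"
            f" (of {len(curve)}); extent {lo} .. {hi} mm"
        )
    step = spacing / _dense_divisor
    dense = (
        curve.resample_step(step) if curve.length > step else curve
    )
    radius = diameter / 2.0
    grid = np.zeros(ref_volume.shape, dtype=np.uint8)
    # restrict the distance query to the tube's bounding box
    pad = radius + spacing
    lo_idx = np.maximum(
        np.floor((dense.points.min(axis=0) - pad - lo) / spacing), 0
    ).astype(int)
    hi_idx = np.minimum(
        np.ceil((dense.points.max(axis=0) + pad - lo) / spacing),
        np.array(ref_volume.shape) - 1,
    ).astype(int)
    axes = [np.arange(lo_idx[k], hi_idx[k] + 1) for k in range(3)]
    box = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centres = lo + box * spacing
    d, _ = cKDTree(dense.points).query(centres, k=1)
    inside = box[d <= radius + 1e-9]
    grid[inside[:, 0], inside[:, 1], inside[:, 2]] = 1
    return VoxelMask(grid=grid, spacing=spacing, origin=ref_volume.origin.copy())


def perturb_annotation(
    centerline: CurveLine,
    n_points: int,
    jitter_sd: float,
    rng: np.random.Generator,
    side: str = "unspecified",
) -> ControlPointPath:
    """Synthesise a coarse control-point annotation from an exact centerline.

    ``n_points`` are taken at uniform arc-length positions along the true
    centerline and displaced by isotropic Gaussian jitter of SD
    ``jitter_sd`` mm, emulating a reader's sparse, imprecise point placement.
    """
    if n_points < 2:
        raise ValueError("need at least 2 control points")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    base = centerline.resample_n(n_points).points
    if jitter_sd > 0:
        base = base + rng.normal(0.0, jitter_sd, size=base.shape)
    # jitter can in principle collapse neighbours; nudge any duplicates
    gaps = np.linalg.norm(np.diff(base, axis=0), axis=1)
    for i in np.where(gaps == 0)[0]:
        base[i + 1, 0] += 1e-9
    return ControlPointPath(points=base, side=side)


# ---------------------------------------------------------------------------
# control-point file I/O (CSV with header, or JSON)
# ---------------------------------------------------------------------------


def write_control_points(path: ControlPointPath, file) -> None:
    file = pathlib.Path(file)
    if file.suffix == ".json":
        file.write_text(
            json.dumps(
                {"side": path.side, "points_mm": path.points.tolist()}, indent=1
            )
        )
    else:
        header = "x_mm,y_mm,z_mm"
        np.savetxt(
            file, path.points, delimiter=",", header=header, comments="", fmt="%.9g"
        )


def read_control_points(file, side: str = "unspecified") -> ControlPointPath:
    file = pathlib.Path(file)
    if not file.exists():
        raise FileNotFoundError(f"control-point file not found: {file}")
    if file.suffix == ".json":
        data = json.loads(file.read_text())
        return ControlPointPath(
            np.asarray(data["points_mm"], dtype=float),
            side=data.get("side", side),
        )
    pts = np.loadtxt(file, delimiter=",", skiprows=1, ndmin=2)
    return ControlPointPath(pts, side=side)
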