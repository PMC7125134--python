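"""Segmentation performance measures.

Voxel-overlap measures (Dice similarity coefficient, precision, recall) are
computed from exact confusion counts. Three distance measures complement
them, all in millimetres:

* ASSD — average symmetric surface distance: the mean nearest-neighbour
  distance between the two surface voxel sets, symmetrised over both
  directions.
* MCD — mean curve distance: the mean distance from ground-truth centerline
  points to the predicted centerline. Deliberately asymmetric
  (ground truth -> prediction), since the clinically relevant question is how
  far the true nerve path is from the predicted one.
* RHD — robust Hausdorff distance: the maximum of the two directed
  95th-percentile surface distances, a Hausdorff variant insensitive to a
  few outlier voxels.

Surfaces are mask voxels with at least one of their 6 face-neighbours
outside the mask (the volume border counts as outside). Centerlines of
predicted masks are extracted by 3D thinning followed by a longest-path
traversal of the skeleton graph.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import networkx as nx
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .curves import CurveLine
from .volume import VoxelMask

#: distance reported for a canal whose prediction (or truth) is empty; kept
#: as NaN so summaries can count failures instead of silently dropping them.
FAILED_DISTANCE = float("nan")


@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclasses.dataclass
class MetricReport:
    """Per-canal evaluation row: overlap measures and distances (mm)."""

    side: str
    dsc: float
    precision: float
    recall: float
    mcd: float
    assd: float
    rhd: float
    failed: bool = False


def confusion(pred: VoxelMask, truth: VoxelMask) -> ConfusionCounts:
    """Exact voxelwise confusion counts between aligned binary masks."""
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    p = pred.grid.astype(bool)
    t = truth.grid.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN); NaN when undefined."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return float("nan")
    return 2 * c.TP / denom


def precision(c: ConfusionCounts) -> float:
    denom = c.TP + c.FP
    if denom == 0:
        return float("nan")
    return c.TP / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.TP + c.FN
    if denom == 0:
        return float("nan")
    return c.TP / denom


# ---------------------------------------------------------------------------
# surfaces and surface distances
# ---------------------------------------------------------------------------


def surface_indices(mask: VoxelMask) -> np.ndarray:
    """Voxel indices (N, 3) of mask voxels with an outside 6-face-neighbour."""
    g = mask.grid.astype(bool)
    if not g.any():
        raise ValueError("surface of an empty mask is undefined")
    padded = np.pad(g, 1)
    interior = np.ones_like(g)
    for axis in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    surf = g & ~interior
    return np.argwhere(surf)


def extract_surface(mask: VoxelMask) -> np.ndarray:
    """Surface voxel coordinates in mm, shape (N, 3)."""
    return mask.voxel_to_mm(surface_indices(mask))


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-neighbour Euclidean distance from each point of a to the set b."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def assd(pred: VoxelMask, truth: VoxelMask) -> float:
    """Average symmetric surface distance in mm.

    ``(sum_t d(t, S(P)) + sum_p d(p, S(T))) / (|S(T)| + |S(P)|)`` with d the
    Euclidean nearest-neighbour distance between surface voxel centres.
    Returns the failure marker (NaN) if either mask is empty.
    """
    if not pred.grid.any() or not truth.grid.any():
        return FAILED_DISTANCE
    sp = extract_surface(pred)
    st = extract_surface(truth)
    d_ts = _directed_distances(st, sp)
    d_ps = _directed_distances(sp, st)
    return float((d_ts.sum() + d_ps.sum()) / (len(st) + len(sp)))


def rhd(pred: VoxelMask, truth: VoxelMask) -> float:
    """Robust (95th-percentile) Hausdorff distance in mm.

    Maximum of the two directed 95th percentiles of surface-to-surface
    nearest-neighbour distances; percentiles interpolate linearly between
    order statistics.
    """
    if not pred.grid.any() or not truth.grid.any():
        return FAILED_DISTANCE
    sp = extract_surface(pred)
    st = extract_surface(truth)
    d_ts = _directed_distances(st, sp)
    d_ps = _directed_distances(sp, st)
    return float(
        max(np.percentile(d_ts, 95), np.percentile(d_ps, 95))
    )


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

_NEIGHBOUR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def skeleton_curve(mask: VoxelMask) -> CurveLine:
    """Extract an ordered centerline from a single tubular component.

    The mask is thinned to a 1-voxel skeleton; the skeleton voxels form a
    26-connected graph (edges weighted by Euclidean gap) whose longest
    geodesic path, found by a double Dijkstra sweep, is returned ordered
    from one endpoint to the other. Side branches off the main path are
    discarded.
    """
    g = mask.grid.astype(bool)
    if not g.any():
        raise ValueError("cannot skeletonize an empty mask")
    n_comp = ndimage.label(g, structure=np.ones((3, 3, 3)))[1]
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; apply the "
            "connected-component post-processing first"
        )
    skel = skeletonize(g)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        # thinning collapsed a blob to <2 voxels; fall back to the mask's
        # principal axis through its two extreme voxels
        pts = mask.voxel_to_mm(np.argwhere(g))
        centred = pts - pts.mean(axis=0)
        axis = np.linalg.svd(centred, full_matrices=False)[2][0]
        proj = centred @ axis
        return CurveLine(np.array([pts[proj.argmin()], pts[proj.argmax()]]))

    index = {tuple(c): i for i, c in enumerate(coords)}
    graph = nx.Graph()
    graph.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for off in _NEIGHBOUR_OFFSETS:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                graph.add_edge(i, j, weight=float(np.linalg.norm(off)))

    def farthest(src: int) -> int:
        dist = nx.single_source_dijkstra_path_length(graph, src)
        return max(dist, key=dist.get)  # type: ignore[arg-type]

    u = farthest(0)
    v = farthest(u)
    path = nx.dijkstra_path(graph, u, v)
    pts = mask.voxel_to_mm(coords[path])
    if len(pts) < 2:
        pts = np.vstack([pts, pts + mask.spacing * 1e-3])
    return CurveLine(pts)


def skeleton_endpoint_count(mask: VoxelMask) -> int:
    """Number of degree-1 voxels in the 26-connected skeleton graph."""
    g = mask.grid.astype(bool)
    skel = skeletonize(g)
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    degrees = np.zeros(len(coords), dtype=int)
    for i, c in enumerate(coords):
        for off in _NEIGHBOUR_OFFSETS:
            if tuple(c + off) in index:
                degrees[i] += 1
    return int(np.count_nonzero(degrees == 1))


def mcd(truth_curve: CurveLine, pred_curve: CurveLine) -> float:
    """Mean curve distance in mm: mean over ground-truth curve points of the
    nearest-point distance to the predicted curve. Asymmetric by design."""
    d = _directed_distances(truth_curve.points, pred_curve.points)
    return float(d.mean())


# ---------------------------------------------------------------------------
# per-case evaluation
# ---------------------------------------------------------------------------


def evaluate_canal(
    pred: VoxelMask | None,
    truth: VoxelMask,
    truth_curve: CurveLine,
    side: str = "unspecified",
) -> MetricReport:
    """All six measures for one canal; failures are marked, never dropped.

    MCD compares the ground-truth centerline against the skeleton of the
    predicted mask, mirroring the asymmetry between an exact reference curve
    and a model output.
    """
    if pred is None or not pred.grid.any():
        empty = VoxelMask(
            np.zeros(truth.shape, dtype=np.uint8), truth.spacing, truth.origin
        )
        c = confusion(empty, truth)
        return MetricReport(
            side=side,
            dsc=dsc(c) if not np.isnan(dsc(c)) else 0.0,
            precision=float("nan"),
            recall=recall(c),
            mcd=FAILED_DISTANCE,
            assd=FAILED_DISTANCE,
            rhd=FAILED_DISTANCE,
            failed=True,
        )
    c = confusion(pred, truth)
    try:
        pred_curve = skeleton_curve(pred)
        mcd_val = mcd(truth_curve, pred_curve)
    except ValueError:
        mcd_val = FAILED_DISTANCE
    return MetricReport(
        side=side,
        dsc=dsc(c),
        precision=precision(c),
        recall=recall(c),
        mcd=mcd_val,
        assd=assd(pred, truth),
        rhd=rhd(pred, truth),
        failed=bool(np.isnan(mcd_val)),
    )


def evaluate_case(
    pred_canals: list[VoxelMask | None],
    truth_canals: list[VoxelMask],
    truth_curves: list[CurveLine],
    sides: list[str] | None = None,
) -> list[MetricReport]:
    """Evaluate paired predicted/ground-truth canals of one scan."""
    if len(truth_canals) != len(truth_curves):
        raise ValueError("need one centerline per ground-truth canal")
    if sides is None:
        sides = (
            ["left", "right"] if len(truth_canals) == 2
            else ["unspecified"] * len(truth_canals)
        )
    reports = []
    for i, (truth, curve) in enumerate(zip(truth_canals, truth_curves)):
        pred = pred_canals[i] if i < len(pred_canals) else None
        reports.append(evaluate_canal(pred, truth, curve, side=sides[i]))
    return reports
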