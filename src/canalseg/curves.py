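"""Ordered 3D polylines in millimetres: canal centerlines and annotation paths."""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class CurveLine:
    """An open, ordered 3D polyline in mm.

    Used for canal centerlines: the first point is the proximal
    (mandibular-foramen) end wherever orientation matters.
    """

    points: np.ndarray  # (N, 3) mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected (N, 3) points, got shape {pts.shape}")
        if len(pts) < 2:
            raise ValueError("a curve needs at least 2 points")
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive curve points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total arc length (mm): sum of consecutive Euclidean gaps."""
        return float(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum()
        )

    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        gaps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(gaps)])

    def reversed(self) -> "CurveLine":
        return CurveLine(self.points[::-1].copy())

    def resample_n(self, n: int) -> "CurveLine":
        """Resample to ``n`` points at equal arc-length increments.

        Endpoints and orientation are preserved; intermediate points are
        linear interpolations along the polyline.
        """
        if n < 2:
            raise ValueError("need n >= 2 resampled points")
        s = self.arclengths()
        if s[-1] <= 0:
            raise ValueError("degenerate curve of zero length")
        targets = np.linspace(0.0, s[-1], n)
        pts = np.column_stack(
            [np.interp(targets, s, self.points[:, k]) for k in range(3)]
        )
        pts[0] = self.points[0]
        pts[-1] = self.points[-1]
        return CurveLine(_dedupe(pts))

    def resample_step(self, step: float) -> "CurveLine":
        """Resample to a uniform arc-length step of at most ``step`` mm."""
        if step <= 0:
            raise ValueError("step must be > 0")
        total = self.length
        if step > total:
            raise ValueError(
                f"step {step} mm exceeds the total path length {total:.3f} mm"
            )
        n = int(np.ceil(total / step)) + 1
        return self.resample_n(n)


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates introduced by interpolation round-off."""
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], gaps > 0])
    out = pts[keep]
    if len(out) < 2:  # fully degenerate input; keep endpoints apart
        raise ValueError("curve collapsed to a single point")
    return out
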