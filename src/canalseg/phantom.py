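"""Synthetic CBCT-like phantoms with exact canal ground truth.

The clinical task — finding a dark (radiolucent) tubular corridor inside
bright cortical/trabecular bone — is emulated at desk scale: each phantom is
an isotropic HU-valued volume containing one or two smooth curved canals of
fixed diameter, rendered dark inside a bright bone-like shell and slab, with
additive Gaussian noise and optional streak artifacts. The generator returns
the exact voxel mask and centerline of every canal, so training, inference
and every distance metric can be validated without clinical data.

Phantoms are not anatomically realistic mandibles and do not simulate CBCT
physics; they provide the local contrast cue and label-noise regime of the
clinical problem in a fully controlled form.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import shutil

import numpy as np
from scipy.spatial import cKDTree

from . import annotation as ann
from .curves import CurveLine
from .volume import HU_MAX, HU_MIN, Volume, VoxelMask, write_mask, write_volume


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    Intensities are in HU: tissue background 0, bone 1500, canal interior
    200 (a dark corridor inside bright bone), noise SD 100 — plausible CBCT
    scale values chosen for a clearly learnable but non-trivial contrast.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 0.4
    n_canals: int = 2
    canal_diameter: float = 3.0
    curve_amplitude: float = 2.5
    bone_intensity: float = 1500.0
    tissue_intensity: float = 0.0
    canal_intensity: float = 200.0
    noise_sd: float = 100.0
    artifact_level: float = 0.0
    seed: int = 0
    shell_thickness: float = 2.0  # bright bone collar around each canal (mm)
    slab_half_mm: float = 5.0  # half-thickness of the bone slab (mm)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError(f"implausible phantom shape {self.shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.canal_diameter <= 2 * self.spacing:
            raise ValueError(
                "canal_diameter must exceed 2 voxels to be resolvable "
                f"(got {self.canal_diameter} mm at {self.spacing} mm spacing)"
            )
        if not (self.bone_intensity > self.tissue_intensity):
            raise ValueError("bone_intensity must exceed tissue_intensity")
        if not (self.bone_intensity > self.canal_intensity):
            raise ValueError("canal must be darker than bone")
        if self.canal_intensity < HU_MIN:
            raise ValueError("canal_intensity below the HU floor")
        if self.n_canals not in (1, 2):
            raise ValueError("n_canals must be 1 or 2")
        if self.artifact_level < 0 or self.noise_sd < 0:
            raise ValueError("noise_sd and artifact_level must be >= 0")

    @property
    def extent(self) -> np.ndarray:
        """Physical positions of the last voxel centre per axis (mm)."""
        return (np.array(self.shape) - 1) * self.spacing


@dataclasses.dataclass
class PhantomSample:
    """One generated phantom: image, per-canal truth masks and centerlines.

    Centerlines are ordered from the proximal ("mandibular-foramen") end to
    the distal ("mental-foramen") end; canals are ordered by their position
    along the left-right axis (axis 1).
    """

    volume: Volume
    truth_masks: list[VoxelMask]
    centerlines: list[CurveLine]


LR_AXIS = 1  # canals are laid out in separate lanes along axis 1


def sample_canal_curve(
    spec: PhantomSpec, rng: np.random.Generator, lane: int = 0
) -> CurveLine:
    """Draw one smooth open canal curve inside the volume interior.

    The curve runs along axis 0 between 4-8 spline knots whose transverse
    coordinates wander by at most ``curve_amplitude`` mm around a lane
    centre; with two canals the lanes are separated so the curves keep a
    clearance of at least twice the canal diameter.
    """
    extent = spec.extent
    radius = spec.canal_diameter / 2.0
    margin = radius + 2 * spec.spacing + 1e-6
    usable = extent[0] - 2 * margin
    if usable < 30 * spec.spacing:
        raise ValueError(
            f"volume extent {extent[0]:.1f} mm cannot fit a canal of length "
            f">= {30 * spec.spacing:.1f} mm at clearance {margin:.1f} mm"
        )
    amp = min(spec.curve_amplitude, _max_amplitude(spec))
    n_knots = int(rng.integers(4, 9))
    x = margin + usable * np.linspace(0.0, 1.0, n_knots)
    lane_centre = _lane_centres(spec)[lane]
    y = lane_centre + rng.uniform(-amp, amp, size=n_knots)
    z = extent[2] / 2.0 + rng.uniform(-amp, amp, size=n_knots)
    lo = margin
    y = np.clip(y, lo, extent[1] - lo)
    z = np.clip(z, lo, extent[2] - lo)
    knots = np.column_stack([x, y, z])
    curve = ann.interpolate_path(
        ann.ControlPointPath(knots), step=spec.spacing / 2.0
    )
    if curve.length < 30 * spec.spacing:
        raise ValueError("sampled curve shorter than the 30-voxel minimum")
    return curve


def _lane_centres(spec: PhantomSpec) -> list[float]:
    ey = spec.extent[LR_AXIS]
    if spec.n_canals == 1:
        return [ey / 2.0]
    return [0.32 * ey, 0.68 * ey]


def _max_amplitude(spec: PhantomSpec) -> float:
    """Largest knot wander that keeps two canals at >= 2 diameters clearance."""
    if spec.n_canals == 1:
        return spec.curve_amplitude
    gap = 0.36 * spec.extent[LR_AXIS]
    slack = gap - 2.0 * spec.canal_diameter
    if slack <= 0:
        raise ValueError(
            "volume too small to fit two canals at twice-diameter clearance"
        )
    return max(min(spec.curve_amplitude, slack / 2.0 - 0.2), 0.0)


def sample_curves(spec: PhantomSpec, rng: np.random.Generator) -> list[CurveLine]:
    """Draw all canal curves of one phantom, enforcing pairwise clearance."""
    for _ in range(5):
        curves = [
            sample_canal_curve(spec, rng, lane=i) for i in range(spec.n_canals)
        ]
        if spec.n_canals == 1:
            return curves
        d, _ = cKDTree(curves[1].points).query(curves[0].points, k=1)
        if d.min() >= 2.0 * spec.canal_diameter:
            return curves
    raise ValueError(
        "could not place two canals at twice-diameter clearance; "
        "reduce curve_amplitude or enlarge the volume"
    )


def rasterize_phantom(
    spec: PhantomSpec,
    curves: list[CurveLine],
    rng: np.random.Generator | None = None,
) -> PhantomSample:
    """Render curves into an HU volume plus exact truth masks.

    Truth mask: voxel centres within ``canal_diameter / 2`` of the densely
    resampled centerline. Grey values: tissue background; bone in a slab
    around the canals' mean height and in a collar around each canal; the
    canal interior dark; additive Gaussian noise; optional bright streak
    planes; final clip to the valid HU range.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if len(curves) != spec.n_canals:
        raise ValueError("number of curves must match spec.n_canals")
    radius = spec.canal_diameter / 2.0
    shape = spec.shape
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * spec.spacing for n in shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)

    dist = np.empty((len(curves), coords.shape[0]))
    for i, curve in enumerate(curves):
        dense = curve.resample_step(spec.spacing / 4.0)
        dist[i], _ = cKDTree(dense.points).query(coords, k=1)

    canal = dist <= radius + 1e-9
    shell = (dist <= radius + spec.shell_thickness).any(axis=0)
    z = coords[:, 2]
    z_mid = np.mean([c.points[:, 2].mean() for c in curves])
    slab = np.abs(z - z_mid) <= spec.slab_half_mm

    grid = np.full(coords.shape[0], spec.tissue_intensity, dtype=np.float64)
    grid[shell | slab] = spec.bone_intensity
    grid[canal.any(axis=0)] = spec.canal_intensity
    if spec.noise_sd > 0:
        grid += rng.normal(0.0, spec.noise_sd, size=grid.shape)
    if spec.artifact_level > 0:
        n_planes = 1 + int(spec.artifact_level)
        for _ in range(n_planes):
            point = rng.uniform(0, spec.extent)
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            plane = np.abs((coords - point) @ normal) <= spec.spacing / 2.0
            grid[plane] += 500.0 * spec.artifact_level
    grid = np.clip(grid, HU_MIN, HU_MAX).reshape(shape).astype(np.float32)

    masks = [
        VoxelMask(canal[i].reshape(shape).astype(np.uint8), spec.spacing)
        for i in range(len(curves))
    ]
    if len(masks) == 2 and (masks[0].grid & masks[1].grid).any():
        raise ValueError("canal truth masks overlap; clearance check failed")
    order = np.argsort(
        [c.points[:, LR_AXIS].mean() for c in curves]
    )
    return PhantomSample(
        volume=Volume(grid, spec.spacing),
        truth_masks=[masks[i] for i in order],
        centerlines=[curves[i] for i in order],
    )


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Convenience: sample curves and rasterize with the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    return rasterize_phantom(spec, sample_curves(spec, rng), rng)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    spec_template: PhantomSpec,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int,
    out_dir,
    overwrite: bool = False,
    annotation_points: int = 10,
    annotation_jitter_sd: float = 0.5,
    tube_diameter: float = ann.DEFAULT_TUBE_DIAMETER_MM,
) -> dict:
    """Generate a disjoint train/validation/test phantom dataset on disk.

    Every sample gets: the volume (NIfTI), per-canal truth masks and
    centerlines (CSV of ordered x_mm,y_mm,z_mm rows), a synthetic coarse
    control-point annotation per canal (about 10 jittered points) and the
    discretised coarse tube label used for training. Each sample draws its
    randomness from a stream derived from ``(seed, sample index)``, so the
    dataset is reproducible regardless of generation order.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be >= 0")
    out_dir = pathlib.Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {out_dir} is not empty; pass overwrite=True"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    samples = []
    for idx, split in enumerate(splits):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
        rng = np.random.default_rng(ss)
        spec = dataclasses.replace(
            spec_template, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        sample = rasterize_phantom(spec, sample_curves(spec, rng), rng)
        sid = f"phantom_{idx:03d}"
        paths = _write_sample(
            sample, out_dir, sid, rng,
            annotation_points, annotation_jitter_sd, tube_diameter,
        )
        samples.append(
            {
                "id": sid,
                "split": split,
                "n_canals": spec.n_canals,
                "lr_axis": LR_AXIS,
                "paths": paths,
            }
        )

    manifest = {
        "seed": int(seed),
        "spec": dataclasses.asdict(dataclasses.replace(spec_template)),
        "annotation": {
            "n_points": annotation_points,
            "jitter_sd_mm": annotation_jitter_sd,
            "tube_diameter_mm": tube_diameter,
        },
        "samples": samples,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_sample(
    sample: PhantomSample,
    out_dir: pathlib.Path,
    sid: str,
    rng: np.random.Generator,
    n_points: int,
    jitter_sd: float,
    tube_diameter: float,
) -> dict:
    paths: dict = {"volume": f"{sid}_volume.nii.gz", "truth_masks": [],
                   "centerlines": [], "coarse_points": []}
    write_volume(sample.volume, out_dir / paths["volume"])
    coarse_union = np.zeros(sample.volume.shape, dtype=np.uint8)
    sides = ["left", "right"][: len(sample.truth_masks)]
    for k, (mask, curve) in enumerate(
        zip(sample.truth_masks, sample.centerlines)
    ):
        mp = f"{sid}_canal{k}_mask.nii.gz"
        cp = f"{sid}_canal{k}_centerline.csv"
        pp = f"{sid}_canal{k}_points.csv"
        write_mask(mask, out_dir / mp)
        np.savetxt(
            out_dir / cp, curve.points, delimiter=",",
            header="x_mm,y_mm,z_mm", comments="", fmt="%.9g",
        )
        path = ann.perturb_annotation(
            curve, n_points, jitter_sd, rng, side=sides[k]
        )
        # keep jittered control points inside the volume so the tube rasterises
        path.points.clip(
            sample.volume.origin,
            sample.volume.origin
            + (np.array(sample.volume.shape) - 1) * sample.volume.spacing,
            out=path.points,
        )
        ann.write_control_points(path, out_dir / pp)
        coarse_curve = ann.interpolate_path(path, step=sample.volume.spacing / 2)
        coarse = ann.tube_mask(coarse_curve, tube_diameter, sample.volume)
        coarse_union |= coarse.grid
        paths["truth_masks"].append(mp)
        paths["centerlines"].append(cp)
        paths["coarse_points"].append(pp)
    paths["coarse_mask"] = f"{sid}_coarse_mask.nii.gz"
    write_mask(
        VoxelMask(coarse_union, sample.volume.spacing, sample.volume.origin),
        out_dir / paths["coarse_mask"],
    )
    return paths


def load_sample(entry: dict, base_dir) -> dict:
    """Load one manifest entry back into in-memory objects."""
    from .volume import read_mask, read_volume

    base = pathlib.Path(base_dir)
    p = entry["paths"]
    return {
        "id": entry["id"],
        "n_canals": entry["n_canals"],
        "lr_axis": entry.get("lr_axis", LR_AXIS),
        "volume": read_volume(base / p["volume"]),
        "truth_masks": [read_mask(base / m) for m in p["truth_masks"]],
        "centerlines": [
            CurveLine(np.loadtxt(base / c, delimiter=",", skiprows=1, ndmin=2))
            for c in p["centerlines"]
        ],
        "coarse_mask": read_mask(base / p["coarse_mask"]),
    }
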