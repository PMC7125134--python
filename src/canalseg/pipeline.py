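"""Reproducible end-to-end runs driven by a single configuration.

Stages: generate -> preprocess -> train -> predict -> evaluate -> profile.
Every stage appends a completion record (stage name, config hash, seed,
outputs) to ``run_log.json`` in the output directory. All randomness is
derived from explicit seeds in the configuration, so rerunning an identical
configuration reproduces identical metric reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import yaml

from . import annotation as ann
from . import metrics as met
from . import phantom as ph
from .curves import CurveLine
from .inference import binarize, keep_largest_components, predict_volume, split_canals
from .model import CanalNet, ModelConfig, build_model
from .patches import extract_training_patches
from .profiles import aggregate_profiles, profile_case, resample_uniform
from .train import TrainConfig, train
from .volume import (
    VoxelMask,
    clip_hu,
    normalize,
    read_mask,
    read_volume,
    resample_isotropic,
    resample_mask,
    write_mask,
    write_volume,
)

STAGES = ["generate", "preprocess", "train", "predict", "evaluate", "profile"]


@dataclasses.dataclass
class DatasetConfig:
    n_train: int = 20
    n_val: int = 0
    n_test: int = 4
    annotation_points: int = 10
    annotation_jitter_sd: float = 0.5
    tube_diameter: float = ann.DEFAULT_TUBE_DIAMETER_MM
    overwrite: bool = True


@dataclasses.dataclass
class InferenceConfig:
    threshold: float = 0.5
    tile: int = 32
    stride: int = 22

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclasses.dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    output_dir: str = "canalseg_run"
    seed: int = 0
    target_spacing: float = 0.4
    phantom: ph.PhantomSpec = dataclasses.field(default_factory=ph.PhantomSpec)
    dataset: DatasetConfig = dataclasses.field(default_factory=DatasetConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    inference: InferenceConfig = dataclasses.field(default_factory=InferenceConfig)

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sections = {
            "phantom": ph.PhantomSpec,
            "dataset": DatasetConfig,
            "model": ModelConfig,
            "training": TrainConfig,
            "inference": InferenceConfig,
        }
        kwargs: dict = {}
        for name, typ in sections.items():
            sub = raw.pop(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"section '{name}' must be a mapping")
            _reject_unknown(sub, typ, name)
            if name == "phantom" and "shape" in sub:
                sub = dict(sub, shape=tuple(sub["shape"]))
            kwargs[name] = typ(**sub)
        _reject_unknown(
            raw, cls, "top level", skip=set(sections)
        )
        return cls(**kwargs, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _reject_unknown(sub: dict, typ, name: str, skip: set | None = None) -> None:
    fields = {f.name for f in dataclasses.fields(typ)}
    unknown = set(sub) - fields - (skip or set())
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{name}'"
        )


def desk_scale_run_config(output_dir: str, seed: int = 0) -> RunConfig:
    """The standard single-CPU phantom experiment configuration."""
    return RunConfig(
        output_dir=output_dir,
        seed=seed,
        phantom=ph.PhantomSpec(),
        dataset=DatasetConfig(),
        model=ModelConfig(n_levels=2, base_channels=8),
        training=TrainConfig(seed=seed, scaled_down=True),
        inference=InferenceConfig(),
    )


class PipelineRun:
    """Executes stages and keeps the run log."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = pathlib.Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_path = self.out / "run_log.json"

    # -- logging ------------------------------------------------------------

    def _log(self, stage: str, outputs: list[str]) -> None:
        records = []
        if self.log_path.exists():
            records = json.loads(self.log_path.read_text())
        records = [r for r in records if r["stage"] != stage]
        records.append(
            {
                "stage": stage,
                "config_hash": self.config.config_hash(),
                "seed": self.config.seed,
                "outputs": outputs,
            }
        )
        self.log_path.write_text(json.dumps(records, indent=1))

    def _manifest(self) -> dict:
        path = self.out / "data" / "manifest.json"
        if not path.exists():
            raise FileNotFoundError(
                "missing artifact data/manifest.json; run the 'generate' stage first"
            )
        return json.loads(path.read_text())

    def _samples(self, split: str) -> list[dict]:
        return [
            s for s in self._manifest()["samples"] if s["split"] == split
        ]

    # -- stages -------------------------------------------------------------

    def generate(self) -> None:
        cfg = self.config
        ph.generate_dataset(
            cfg.phantom,
            cfg.dataset.n_train,
            cfg.dataset.n_val,
            cfg.dataset.n_test,
            seed=cfg.seed,
            out_dir=self.out / "data",
            overwrite=cfg.dataset.overwrite,
            annotation_points=cfg.dataset.annotation_points,
            annotation_jitter_sd=cfg.dataset.annotation_jitter_sd,
            tube_diameter=cfg.dataset.tube_diameter,
        )
        self._log("generate", ["data/manifest.json"])

    def preprocess(self) -> None:
        prep = self.out / "prep"
        prep.mkdir(exist_ok=True)
        outputs = []
        for s in self._manifest()["samples"]:
            vol = read_volume(self.out / "data" / s["paths"]["volume"])
            vol = normalize(
                clip_hu(resample_isotropic(vol, self.config.target_spacing))
            )
            name = f"{s['id']}_prep.nii.gz"
            write_volume(vol, prep / name)
            outputs.append(f"prep/{name}")
            # carry the training label onto the preprocessed grid
            coarse = read_mask(self.out / "data" / s["paths"]["coarse_mask"])
            coarse = resample_mask(coarse, self.config.target_spacing)
            cname = f"{s['id']}_coarse_prep.nii.gz"
            write_mask(coarse, prep / cname)
            outputs.append(f"prep/{cname}")
        self._log("preprocess", outputs)

    def _prep_pair(self, s: dict):
        vol = read_volume(self.out / "prep" / f"{s['id']}_prep.nii.gz")
        lab = read_mask(self.out / "prep" / f"{s['id']}_coarse_prep.nii.gz")
        return vol, lab

    def train(self) -> CanalNet:
        patches = []
        for s in self._samples("train"):
            vol, lab = self._prep_pair(s)
            patches.extend(extract_training_patches(vol, lab))
        val = [self._prep_pair(s) for s in self._samples("val")] or None
        model = build_model(self.config.model, seed=self.config.seed)
        model, history = train(model, patches, val, self.config.training)
        model.save(self.out / "model.npz")
        (self.out / "history.json").write_text(json.dumps(history, indent=1))
        self._log("train", ["model.npz", "history.json"])
        return model

    def predict(self, model: CanalNet | None = None) -> None:
        if model is None:
            model_path = self.out / "model.npz"
            if not model_path.exists():
                raise FileNotFoundError(
                    "missing artifact model.npz; run the 'train' stage first"
                )
            model = CanalNet.load(model_path)
        pred_dir = self.out / "pred"
        pred_dir.mkdir(exist_ok=True)
        icfg = self.config.inference
        outputs = []
        for s in self._samples("test"):
            vol, _ = self._prep_pair(s)
            probs = predict_volume(
                model, vol, tile=icfg.tile, overlap_stride=icfg.stride
            )
            mask = binarize(probs, icfg.threshold)
            mask, warned = keep_largest_components(mask, s["n_canals"])
            name = f"{s['id']}_pred.nii.gz"
            write_mask(mask, pred_dir / name)
            outputs.append(f"pred/{name}")
            if warned:
                outputs.append(f"pred/{s['id']}: EMPTY PREDICTION")
        self._log("predict", outputs)

    def _case_reports(self) -> list[tuple[dict, list[met.MetricReport]]]:
        rows = []
        for s in self._samples("test"):
            pred = read_mask(self.out / "pred" / f"{s['id']}_pred.nii.gz")
            pred_canals: list[VoxelMask | None] = (
                list(split_canals(pred, lr_axis=s["lr_axis"]))
                if pred.grid.any()
                else []
            )
            truth = [
                read_mask(self.out / "data" / m) for m in s["paths"]["truth_masks"]
            ]
            curves = [
                CurveLine(np.loadtxt(self.out / "data" / c, delimiter=",",
                                     skiprows=1, ndmin=2))
                for c in s["paths"]["centerlines"]
            ]
            if self.config.target_spacing != self.config.phantom.spacing:
                truth = [
                    resample_mask(m, self.config.target_spacing) for m in truth
                ]
            reports = met.evaluate_case(pred_canals, truth, curves)
            rows.append((s, reports))
        return rows

    def evaluate(self) -> "pathlib.Path":
        import pandas as pd

        per_case = self._case_reports()
        records = []
        for s, reports in per_case:
            row: dict = {"Scan": s["id"], "VS": self.config.target_spacing}
            for rep in reports:
                side = rep.side.capitalize()
                row[f"{side} DSC"] = rep.dsc
                row[f"{side} MCD (mm)"] = rep.mcd
                row[f"{side} ASSD (mm)"] = rep.assd
                row[f"{side} RHD (mm)"] = rep.rhd
                row[f"{side} failed"] = int(rep.failed)
            records.append(row)
        df = pd.DataFrame(records)
        num = df.select_dtypes("number").drop(columns=["VS"])
        mean_row = {"Scan": "Mean", **num.mean().to_dict()}
        sd_row = {"Scan": "SD", **num.std(ddof=0).to_dict()}
        df = pd.concat(
            [df, pd.DataFrame([mean_row, sd_row])], ignore_index=True
        )
        out = self.out / "metrics.csv"
        df.to_csv(out, index=False, float_format="%.6f")
        self._log("evaluate", ["metrics.csv"])
        return out

    def profile(self) -> "pathlib.Path":
        per_case = self._case_reports()
        profiles = []
        for s, _ in per_case:
            pred = read_mask(self.out / "pred" / f"{s['id']}_pred.nii.gz")
            pred_canals = (
                list(split_canals(pred, lr_axis=s["lr_axis"]))
                if pred.grid.any()
                else []
            )
            curves = [
                CurveLine(np.loadtxt(self.out / "data" / c, delimiter=",",
                                     skiprows=1, ndmin=2))
                for c in s["paths"]["centerlines"]
            ]
            for k, curve in enumerate(curves):
                pred_curve = None
                if k < len(pred_canals) and pred_canals[k].grid.any():
                    try:
                        pred_curve = met.skeleton_curve(pred_canals[k])
                    except ValueError:
                        pred_curve = None
                profiles.append(profile_case(curve, pred_curve))
        agg = aggregate_profiles(profiles)
        out = self.out / "profile.csv"
        agg.to_dataframe().to_csv(out, index=False, float_format="%.6f")
        self._log("profile", ["profile.csv"])
        return out


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> pathlib.Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    run = PipelineRun(config)
    model = None
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "train":
            model = run.train()
        elif stage == "predict":
            run.predict(model)
        else:
            getattr(run, stage)()
    return run.out
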