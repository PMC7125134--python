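import numpy as np
import pytest

from canalseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A single-canal noiseless phantom used by several geometry tests."""
    spec = PhantomSpec(
        shape=(48, 48, 48), spacing=0.4, n_canals=1, noise_sd=0.0,
        curve_amplitude=1.0, seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """Two identically seed-pinned end-to-end desk-scale runs.

    Expensive (several minutes each); shared by the end-to-end recovery,
    determinism and profile-identity tests. Also computes the evaluation of
    an untrained network on the same test phantoms as a baseline.
    """
    import pandas as pd

    from canalseg.inference import (
        binarize,
        keep_largest_components,
        predict_volume,
        split_canals,
    )
    from canalseg import metrics as met
    from canalseg.curves import CurveLine
    from canalseg.model import build_model
    from canalseg.pipeline import PipelineRun, desk_scale_run_config, run_pipeline
    from canalseg.volume import read_mask, read_volume

    base = tmp_path_factory.mktemp("desk")
    dirs = []
    for name in ("a", "b"):
        cfg = desk_scale_run_config(str(base / name), seed=11)
        dirs.append(run_pipeline(cfg))

    # untrained baseline on run a's test phantoms
    cfg = desk_scale_run_config(str(base / "a"), seed=11)
    run = PipelineRun(cfg)
    model = build_model(cfg.model, seed=cfg.seed)
    baseline = []
    for s in run._samples("test"):
        vol = read_volume(run.out / "prep" / f"{s['id']}_prep.nii.gz")
        probs = predict_volume(model, vol)
        mask, _ = keep_largest_components(binarize(probs), s["n_canals"])
        preds = list(split_canals(mask, lr_axis=s["lr_axis"])) if mask.grid.any() else []
        truth = [read_mask(run.out / "data" / m) for m in s["paths"]["truth_masks"]]
        curves = [
            CurveLine(np.loadtxt(run.out / "data" / c, delimiter=",",
                                 skiprows=1, ndmin=2))
            for c in s["paths"]["centerlines"]
        ]
        baseline.extend(met.evaluate_case(preds, truth, curves))
    metrics_a = pd.read_csv(dirs[0] / "metrics.csv")
    return {
        "dir_a": dirs[0],
        "dir_b": dirs[1],
        "metrics_a": metrics_a,
        "untrained": baseline,
    }
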