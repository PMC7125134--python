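"""Soft-Dice training of the canal network with Adam.

The loss is the negated soft Dice coefficient

    DL = -2 * sum_n t_n p_n / (sum_n (t_n + p_n) + eps)

summed over every voxel of the mini-batch jointly (batch-pooled numerator
and denominator), with a small ``eps`` defining the all-empty case. The
value lies in [-1, 0]; minimising it maximises overlap with the (coarse)
training labels, and the ratio form keeps the rare canal class from being
swamped by background. At the bridge between training and evaluation:
with ``eps = 0`` and binary predictions the loss equals minus the Dice
similarity coefficient.

Full-scale hyperparameters: 400 epochs, batch 24, Adam at learning rate
1e-4 (beta1 0.9, beta2 0.999). The ``scaled_down`` flag switches to the
desk-scale schedule (20 epochs, batch 8, learning rate 1e-3, at most 48
patches) used throughout the phantom experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .model import CanalNet
from .patches import Patch, augment_flip

DICE_EPS = 1e-6


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 400
    batch_size: int = 24
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    scaled_down: bool = False
    max_patches: int | None = None
    val_interval: int = 5
    augment: bool = True  # random flips; disable for strict no-op checks

    def __post_init__(self) -> None:
        if self.scaled_down:
            # replace full-scale defaults the user did not override
            if self.epochs == 400:
                self.epochs = 20
            if self.batch_size == 24:
                self.batch_size = 8
            if self.learning_rate == 1e-4:
                self.learning_rate = 1e-3
            if self.max_patches is None:
                self.max_patches = 48
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must lie in [0, 1)")


def dice_loss(
    probs: np.ndarray, targets: np.ndarray, eps: float = DICE_EPS
) -> float:
    """Soft-Dice loss over all voxels of the given blocks; value in [-1, 0]."""
    if probs.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs targets {targets.shape}"
        )
    t = targets.astype(np.float64)
    p = probs.astype(np.float64)
    num = float((t * p).sum())
    den = float((t + p).sum()) + eps
    return -2.0 * num / den


def dice_loss_grad(
    probs: np.ndarray, targets: np.ndarray, eps: float = DICE_EPS
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``probs``."""
    if probs.shape != targets.shape:
        raise ValueError("shape mismatch between probs and targets")
    t = targets.astype(np.float64)
    p = probs.astype(np.float64)
    num = (t * p).sum()
    den = (t + p).sum() + eps
    loss = -2.0 * num / den
    grad = (-2.0 * t / den + 2.0 * num / den**2).astype(np.float32)
    return float(loss), grad


def train(
    model: CanalNet,
    train_patches: list[Patch],
    val_volumes=None,
    config: TrainConfig | None = None,
) -> tuple[CanalNet, dict]:
    """Train in place; returns the final-epoch model and the history.

    Each epoch shuffles the patch set and draws mini-batches without
    replacement, applying independent random flips per patch. History holds
    the per-epoch mean training loss and, if ``val_volumes`` (pairs of
    preprocessed :class:`~canalseg.volume.Volume` and label
    :class:`~canalseg.volume.VoxelMask`) are given, a validation DSC every
    ``val_interval`` epochs. No model selection is applied: the final-epoch
    weights are returned and the validation history is informational.

    Fully reproducible: all randomness (patch subsampling, shuffling, flips)
    derives from ``config.seed``.
    """
    config = config or TrainConfig()
    if not train_patches:
        raise ValueError("training patch set is empty")
    rng = np.random.default_rng(config.seed)
    patches = list(train_patches)
    if config.max_patches is not None and len(patches) > config.max_patches:
        idx = rng.choice(len(patches), size=config.max_patches, replace=False)
        patches = [patches[i] for i in sorted(idx)]

    opt = nn.Adam(
        model.params(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
    )
    history: dict = {"train_loss": [], "val_dsc": []}
    n = len(patches)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [
                augment_flip(patches[i], rng) if config.augment else patches[i]
                for i in order[start : start + config.batch_size]
            ]
            x = np.stack([b.image for b in batch])[:, None]
            t = np.stack([b.label for b in batch])[:, None]
            probs = model.forward(x, training=True)
            loss, grad = dice_loss_grad(probs, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            model.backward(grad)
            opt.step()
            opt.zero_grad()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_volumes and (
            (epoch + 1) % config.val_interval == 0 or epoch == config.epochs - 1
        ):
            history["val_dsc"].append(
                (epoch, _validation_dsc(model, val_volumes))
            )
    return model, history


def _validation_dsc(model: CanalNet, val_volumes) -> float:
    from . import metrics
    from .inference import binarize, predict_volume

    scores = []
    for volume, mask in val_volumes:
        probs = predict_volume(model, volume)
        pred = binarize(probs)
        d = metrics.dsc(metrics.confusion(pred, mask))
        scores.append(0.0 if np.isnan(d) else d)
    return float(np.mean(scores))
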