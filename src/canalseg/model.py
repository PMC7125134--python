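"""3D fully convolutional encoder-decoder for canal probability maps.

U-net-style architecture: a contracting pathway of residual convolution
blocks separated by stride-2 convolutions, an expanding pathway of stride-2
transpose convolutions mirrored level for level, long skip connections that
concatenate same-resolution feature maps along channels, and a 1x1x1
convolution head with a logistic-sigmoid link producing a per-voxel canal
probability. Every convolution except the head is followed by batch
normalisation and a ReLU.

Each residual block is two 3x3x3 conv+BN+ReLU stages with an additive
shortcut across the block; where input and output channel counts differ the
shortcut is a 1x1x1 projection. The network is fully convolutional: any
input whose spatial size is divisible by ``2**n_levels`` maps to an output
of the same spatial size.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn

#: head bias at initialisation; canal voxels are rare, so the network starts
#: predicting a low probability (sigmoid(-2) ~ 0.12) everywhere
HEAD_BIAS_INIT = -2.0


@dataclasses.dataclass
class ModelConfig:
    """Channel plan of the network.

    ``base_channels`` feature maps at full resolution, multiplied by
    ``channel_growth`` at each of ``n_levels`` down-sampling stages. The
    full-scale default is 3 levels starting at 32 channels; the desk-scale
    configuration (see :func:`desk_scale_config`) uses 2 levels at 8.
    """

    n_levels: int = 3
    base_channels: int = 32
    channel_growth: int = 2
    patch_size: int = 32
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.patch_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} is not divisible by "
                f"2^{self.n_levels}"
            )

    def channels(self, level: int) -> int:
        return self.base_channels * self.channel_growth**level


def desk_scale_config() -> ModelConfig:
    """Configuration small enough to train on a single CPU."""
    return ModelConfig(n_levels=2, base_channels=8)


class _ConvBNReLU:
    def __init__(self, cin, cout, stride, rng, kernel=3, first=False):
        self.conv = nn.Conv3d(
            cin, cout, kernel=kernel, stride=stride, rng=rng,
            needs_input_grad=not first,
        )
        self.bn = nn.BatchNorm3d(cout)
        self.relu = nn.ReLU()
        self.stages = [self.conv, self.bn, self.relu]

    def forward(self, x, training=False):
        for s in self.stages:
            x = s.forward(x, training)
        return x

    def backward(self, gy):
        for s in reversed(self.stages):
            gy = s.backward(gy)
        return gy

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def buffers(self):
        return [b for s in self.stages for b in s.buffers()]


class _UpBNReLU:
    def __init__(self, cin, cout, rng):
        self.up = nn.ConvTranspose3d(cin, cout, rng=rng)
        self.bn = nn.BatchNorm3d(cout)
        self.relu = nn.ReLU()
        self.stages = [self.up, self.bn, self.relu]

    forward = _ConvBNReLU.forward
    backward = _ConvBNReLU.backward
    params = _ConvBNReLU.params
    buffers = _ConvBNReLU.buffers


class _ResBlock:
    """Two conv+BN+ReLU stages with an additive shortcut across the block."""

    def __init__(self, cin, cout, rng, first=False):
        self.stage1 = _ConvBNReLU(cin, cout, 1, rng, first=first)
        self.stage2 = _ConvBNReLU(cout, cout, 1, rng)
        self.proj = (
            None
            if cin == cout
            else nn.Conv3d(
                cin, cout, kernel=1, pad=0, rng=rng,
                needs_input_grad=not first,
            )
        )

    def forward(self, x, training=False):
        h = self.stage2.forward(self.stage1.forward(x, training), training)
        s = x if self.proj is None else self.proj.forward(x, training)
        return h + s

    def backward(self, gy):
        gmain = self.stage1.backward(self.stage2.backward(gy))
        gshort = gy if self.proj is None else self.proj.backward(gy)
        if gmain is None or gshort is None:  # first block: image grad unused
            return None
        return gmain + gshort

    def params(self):
        out = self.stage1.params() + self.stage2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def buffers(self):
        return self.stage1.buffers() + self.stage2.buffers()


class CanalNet:
    """The segmentation network; use :func:`build_model` to construct."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        L = config.n_levels
        ch = [config.channels(l) for l in range(L + 1)]
        self.enc = [
            _ResBlock(
                config.in_channels if l == 0 else ch[l], ch[l], rng,
                first=(l == 0),
            )
            for l in range(L)
        ]
        self.down = [_ConvBNReLU(ch[l], ch[l + 1], 2, rng) for l in range(L)]
        self.bottleneck = _ResBlock(ch[L], ch[L], rng)
        self.up = [_UpBNReLU(ch[l + 1], ch[l], rng) for l in range(L)]
        self.dec = [_ResBlock(2 * ch[l], ch[l], rng) for l in range(L)]
        self.head = nn.Conv3d(
            ch[0], 1, kernel=1, pad=0, rng=rng, bias_init=HEAD_BIAS_INIT
        )
        self._cache = None

    # -- graph traversal ----------------------------------------------------

    def _modules(self):
        yield from self.enc
        yield from self.down
        yield self.bottleneck
        yield from self.up
        yield from self.dec
        yield self.head

    def params(self) -> list[nn.Parameter]:
        return [p for m in self._modules() for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self._modules() for b in m.buffers()]

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map an image batch (B, 1, D, H, W) to canal probabilities in (0,1).

        Spatial sizes must be divisible by ``2**n_levels``. In evaluation
        mode batch normalisation uses running statistics, so the output is a
        deterministic function of the input.
        """
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, D, H, W) input, got {x.shape}")
        div = 2**self.config.n_levels
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {div}; "
                "pad or retile the input"
            )
        # layers run channels-last internally
        h = np.ascontiguousarray(
            np.moveaxis(np.asarray(x, dtype=np.float32), 1, -1)
        )
        L = self.config.n_levels
        skips = []
        for l in range(L):
            h = self.enc[l].forward(h, training)
            skips.append(h)
            h = self.down[l].forward(h, training)
        h = self.bottleneck.forward(h, training)
        for l in reversed(range(L)):
            h = self.up[l].forward(h, training)
            h = np.concatenate([h, skips[l]], axis=-1)
            h = self.dec[l].forward(h, training)
        logits = self.head.forward(h, training)
        probs = nn.sigmoid(logits)
        if training:
            self._cache = probs
        return np.ascontiguousarray(np.moveaxis(probs, -1, 1))

    def backward(self, gprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        probs = self._cache
        if probs is None:
            raise RuntimeError("backward called without a training forward")
        g = np.ascontiguousarray(
            np.moveaxis(gprobs.astype(np.float32), 1, -1)
        ) * (probs * (1.0 - probs))
        g = self.head.backward(g)
        L = self.config.n_levels
        gskips = [None] * L
        for l in range(L):
            g = self.dec[l].backward(g)
            c = self.config.channels(l)
            gup, gskips[l] = g[..., :c], g[..., c:]
            g = self.up[l].backward(np.ascontiguousarray(gup))
        g = self.bottleneck.backward(g)
        for l in reversed(range(L)):
            g = self.down[l].backward(g)
            g = g + gskips[l]
            g = self.enc[l].backward(g)
        self._cache = None

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()] + self.buffers()

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CanalNet":
        data = np.load(path)
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = build_model(cfg)
        targets = model.state_arrays()
        for i, t in enumerate(targets):
            src = data[f"arr_{i}"]
            if src.shape != t.shape:
                raise ValueError("model file does not match its config")
            t[...] = src
        return model


def build_model(config: ModelConfig, seed: int = 0) -> CanalNet:
    """Construct the network with He-style initialisation."""
    return CanalNet(config, np.random.default_rng(seed))
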