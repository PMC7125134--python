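"""Network layers against scipy oracles and numeric differentiation."""

import numpy as np
import pytest
from scipy import ndimage

from canalseg import nn
from canalseg.model import (
    CanalNet,
    ModelConfig,
    build_model,
    desk_scale_config,
)
from canalseg.train import dice_loss_grad


def ndimage_conv(x, weight, bias, stride=1):
    """Reference correlation via scipy, channels-last single batch item."""
    O, C = weight.shape[:2]
    sp = x.shape[:3]
    out = np.zeros(sp + (O,), dtype=np.float64)
    for o in range(O):
        for c in range(C):
            out[..., o] += ndimage.correlate(
                x[..., c].astype(np.float64), weight[o, c].astype(np.float64),
                mode="constant",
            )
        out[..., o] += bias[o]
    if stride > 1:
        out = out[::stride, ::stride, ::stride]
    return out


class TestConvOracle:
    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_scipy_correlate(self, rng, stride):
        conv = nn.Conv3d(3, 4, kernel=3, stride=stride,
                         rng=np.random.default_rng(2))
        x = rng.random((2, 8, 8, 8, 3)).astype(np.float32)
        y = conv.forward(x)
        for b in range(2):
            ref = ndimage_conv(x[b], conv.weight.data, conv.bias.data, stride)
            np.testing.assert_allclose(y[b], ref, atol=1e-5)

    def test_1x1_conv_is_channel_mixing(self, rng):
        conv = nn.Conv3d(3, 2, kernel=1, pad=0, rng=np.random.default_rng(3))
        x = rng.random((1, 4, 4, 4, 3)).astype(np.float32)
        y = conv.forward(x)
        ref = x[0] @ conv.weight.data.reshape(2, 3).T + conv.bias.data
        np.testing.assert_allclose(y[0], ref, atol=1e-6)

    def test_transpose_conv_doubles_and_adjoint(self, rng):
        """Transpose conv is the adjoint of the stride-2 conv backward pass:
        check <conv_T(x), y> == <x, grad_in> numerically via backprop."""
        up = nn.ConvTranspose3d(3, 2, rng=np.random.default_rng(4))
        x = rng.random((1, 4, 4, 4, 3)).astype(np.float32)
        y = up.forward(x, training=True)
        assert y.shape == (1, 8, 8, 8, 2)
        gy = rng.random(y.shape).astype(np.float32)
        gx = up.backward(gy)
        # adjoint identity: <y', gy> has gradient structure <x, gx> for the
        # bias-free linear part
        lin_y = y - up.bias.data
        assert float((lin_y * gy).sum()) == pytest.approx(
            float((x * gx).sum()), rel=1e-3
        )


class TestModel:
    def test_shape_preserved_and_range(self, rng):
        model = build_model(ModelConfig(n_levels=2, base_channels=4), seed=0)
        x = rng.random((1, 1, 32, 32, 32)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == x.shape
        assert (y > 0).all() and (y < 1).all()

    def test_fully_convolutional_other_sizes(self, rng):
        model = build_model(ModelConfig(n_levels=2, base_channels=4), seed=0)
        x = rng.random((1, 1, 64, 32, 32)).astype(np.float32)
        assert model.forward(x).shape == (1, 1, 64, 32, 32)

    def test_indivisible_size_rejected(self, rng):
        model = build_model(ModelConfig(n_levels=2, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.random((1, 1, 30, 32, 32)).astype(np.float32))

    def test_eval_mode_deterministic(self, rng):
        model = build_model(desk_scale_config(), seed=0)
        x = rng.random((1, 1, 32, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_zero_head_outputs_half(self, rng):
        model = build_model(desk_scale_config(), seed=0)
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0
        y = model.forward(rng.random((1, 1, 32, 32, 32)).astype(np.float32))
        np.testing.assert_allclose(y, 0.5, atol=1e-7)

    def test_parameter_count_closed_form(self):
        cfg = ModelConfig(n_levels=2, base_channels=8, channel_growth=2)
        model = build_model(cfg)
        ch = [8, 16, 32]

        def conv_p(cin, cout, k=3):
            return cout * cin * k**3 + cout

        def bn_p(c):
            return 2 * c

        def block_p(cin, cout):
            p = conv_p(cin, cout) + bn_p(cout)
            p += conv_p(cout, cout) + bn_p(cout)
            if cin != cout:
                p += conv_p(cin, cout, k=1)
            return p

        expected = 0
        expected += block_p(1, ch[0]) + block_p(ch[1], ch[1])  # encoder blocks
        expected += conv_p(ch[0], ch[1]) + bn_p(ch[1])  # down 0
        expected += conv_p(ch[1], ch[2]) + bn_p(ch[2])  # down 1
        expected += block_p(ch[2], ch[2])  # bottleneck
        expected += conv_p(ch[2], ch[1]) + bn_p(ch[1])  # up 1
        expected += conv_p(ch[1], ch[0]) + bn_p(ch[0])  # up 0
        expected += block_p(2 * ch[1], ch[1]) + block_p(2 * ch[0], ch[0])
        expected += conv_p(ch[0], 1, k=1)  # head
        assert model.n_params == expected

    def test_gradients_match_numeric_differentiation(self, rng):
        cfg = ModelConfig(n_levels=1, base_channels=2, patch_size=8)
        model = build_model(cfg, seed=1)
        x = rng.random((2, 1, 8, 8, 8)).astype(np.float32)
        t = (rng.random((2, 1, 8, 8, 8)) < 0.1).astype(np.float32)
        probs = model.forward(x, training=True)
        _, g = dice_loss_grad(probs, t)
        model.backward(g)
        params = model.params()
        for pi in range(0, len(params), 4):
            p = params[pi]
            idx = tuple(0 for _ in p.data.shape)
            eps, orig = 1e-3, p.data[idx]
            p.data[idx] = orig + eps
            lp, _ = dice_loss_grad(model.forward(x, training=True), t)
            model._cache = None
            p.data[idx] = orig - eps
            lm, _ = dice_loss_grad(model.forward(x, training=True), t)
            model._cache = None
            p.data[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(
                numeric, abs=max(3e-3 * abs(numeric), 2e-4)
            )

    def test_save_load_round_trip(self, rng, tmp_path):
        model = build_model(desk_scale_config(), seed=3)
        x = rng.random((1, 1, 32, 32, 32)).astype(np.float32)
        y1 = model.forward(x)
        path = tmp_path / "model.npz"
        model.save(path)
        back = CanalNet.load(path)
        np.testing.assert_array_equal(back.forward(x), y1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_levels=3, base_channels=4, patch_size=20)
        with pytest.raises(ValueError):
            ModelConfig(n_levels=0)
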