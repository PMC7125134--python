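import numpy as np
import pytest

from canalseg.inference import (
    ProbabilityVolume,
    binarize,
    keep_largest_components,
    predict_volume,
    split_canals,
)
from canalseg.model import ModelConfig
from canalseg.volume import Volume, VoxelMask


class ConstantModel:
    """Stub network returning a constant probability everywhere."""

    def __init__(self, c=0.3, n_levels=2):
        self.c = c
        self.config = ModelConfig(n_levels=n_levels, base_channels=1)

    def forward(self, x, training=False):
        return np.full_like(x, self.c)


def brute_components(grid):
    """Independent 26-connectivity flood fill."""
    from collections import deque

    shape = grid.shape
    seen = np.zeros(shape, bool)
    comps = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(grid)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.append(v)
            for off in offsets:
                n = tuple(np.add(v, off))
                if all(0 <= n[a] < shape[a] for a in range(3)):
                    if grid[n] and not seen[n]:
                        seen[n] = True
                        q.append(n)
        comps.append(set(comp))
    return comps


class TestPredictVolume:
    def test_constant_model_gives_constant_map(self, rng):
        vol = Volume(rng.random((54, 54, 54)).astype(np.float32), 0.4)
        probs = predict_volume(ConstantModel(0.3), vol)
        np.testing.assert_allclose(probs.grid, 0.3, atol=1e-6)

    def test_disjoint_tiling_equals_mosaic(self, rng):
        vol = Volume(rng.random((64, 64, 64)).astype(np.float32), 0.4)
        probs = predict_volume(ConstantModel(0.8), vol, overlap_stride=32)
        np.testing.assert_allclose(probs.grid, 0.8, atol=1e-6)

    def test_two_strides_agree_for_constant_model(self, rng):
        vol = Volume(rng.random((54, 54, 54)).astype(np.float32), 0.4)
        a = predict_volume(ConstantModel(0.6), vol, overlap_stride=22)
        b = predict_volume(ConstantModel(0.6), vol, overlap_stride=11)
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-6)

    def test_output_in_unit_interval_and_shape(self, rng, small_phantom):
        from canalseg.model import build_model, desk_scale_config
        from canalseg.volume import clip_hu, normalize

        vol = normalize(clip_hu(small_phantom.volume))
        model = build_model(desk_scale_config(), seed=0)
        probs = predict_volume(model, vol)
        assert probs.grid.shape == vol.shape
        assert probs.grid.min() >= 0.0 and probs.grid.max() <= 1.0

    def test_small_volume_advises_padding(self, rng):
        vol = Volume(rng.random((20, 64, 64)).astype(np.float32), 0.4)
        with pytest.raises(ValueError, match="pad"):
            predict_volume(ConstantModel(), vol)

    def test_unnormalised_volume_rejected(self, rng):
        vol = Volume(rng.random((40, 40, 40)) * 1000, 0.4)
        with pytest.raises(ValueError, match="preprocess"):
            predict_volume(ConstantModel(), vol)


class TestBinarize:
    def make_probs(self, grid):
        return ProbabilityVolume(grid.astype(np.float32), 0.4)

    def test_ties_go_to_background(self):
        probs = self.make_probs(np.full((4, 4, 4), 0.5))
        assert binarize(probs, 0.5).count() == 0

    def test_anti_monotone_in_threshold(self, rng):
        probs = self.make_probs(rng.random((6, 6, 6)))
        hi = binarize(probs, 0.999).grid
        lo = binarize(probs, 0.001).grid
        assert (lo >= hi).all()

    def test_binary_input_identity_at_half(self, rng):
        g = (rng.random((5, 5, 5)) < 0.4).astype(np.float32)
        np.testing.assert_array_equal(binarize(self.make_probs(g)).grid, g)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_threshold_range_enforced(self, bad):
        probs = self.make_probs(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            binarize(probs, bad)


class TestKeepLargestComponents:
    def test_matches_brute_force_flood_fill(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(5, 17, 3))
            g = (rng.random(shape) < 0.15).astype(np.uint8)
            mask = VoxelMask(g, 0.4)
            for n in (1, 2):
                kept, warned = keep_largest_components(mask, n)
                comps = brute_components(g)
                comps.sort(key=len, reverse=True)
                if not comps:
                    assert warned and kept.count() == 0
                    continue
                sizes = sorted((len(c) for c in comps), reverse=True)
                # sizes of kept components must equal the n largest (ties in
                # size make the exact voxel choice ambiguous only at equality)
                kept_comps = brute_components(kept.grid)
                assert sorted((len(c) for c in kept_comps), reverse=True) == sizes[:n]
                assert not warned

    def test_explicit_three_component_example(self):
        g = np.zeros((30, 8, 8), np.uint8)
        g[0:10, 0:2, 0:2] = 1  # 40 voxels
        g[14:19, 0:2, 0:2] = 1  # 20 voxels
        g[24, 0, 0] = 1  # 1 voxel
        kept, _ = keep_largest_components(VoxelMask(g, 0.4), 2)
        assert kept.count() == 60
        assert kept.grid[24, 0, 0] == 0

    def test_fewer_components_than_requested(self):
        g = np.zeros((6, 6, 6), np.uint8)
        g[2:4, 2:4, 2:4] = 1
        kept, warned = keep_largest_components(VoxelMask(g, 0.4), 2)
        np.testing.assert_array_equal(kept.grid, g)
        assert not warned

    def test_empty_mask_warns(self):
        kept, warned = keep_largest_components(
            VoxelMask(np.zeros((4, 4, 4), np.uint8), 0.4), 2
        )
        assert warned and kept.count() == 0

    def test_output_subset_with_bounded_components(self, rng):
        g = (rng.random((14, 14, 14)) < 0.2).astype(np.uint8)
        kept, _ = keep_largest_components(VoxelMask(g, 0.4), 2)
        assert (kept.grid <= g).all()
        assert len(brute_components(kept.grid)) <= 2


class TestSplitCanals:
    def two_tubes(self):
        g = np.zeros((20, 20, 20), np.uint8)
        g[2:18, 3:6, 8:11] = 1
        g[2:18, 13:16, 8:11] = 1
        return VoxelMask(g, 0.4)

    def test_partition_of_two_tubes(self):
        mask = self.two_tubes()
        parts = split_canals(mask, lr_axis=1)
        assert len(parts) == 2
        union = parts[0].grid | parts[1].grid
        np.testing.assert_array_equal(union, mask.grid)
        assert not (parts[0].grid & parts[1].grid).any()

    def test_ordering_along_lr_axis_and_mirror(self):
        mask = self.two_tubes()
        parts = split_canals(mask, lr_axis=1)
        assert parts[0].grid[:, 3:6].any() and not parts[0].grid[:, 13:16].any()
        mirrored = VoxelMask(mask.grid[:, ::-1].copy(), 0.4)
        mparts = split_canals(mirrored, lr_axis=1)
        np.testing.assert_array_equal(
            mparts[0].grid, parts[1].grid[:, ::-1]
        )

    def test_single_tube_singleton(self):
        g = np.zeros((10, 10, 10), np.uint8)
        g[2:8, 4:6, 4:6] = 1
        assert len(split_canals(VoxelMask(g, 0.4))) == 1

    def test_more_than_two_components_rejected(self):
        g = np.zeros((12, 12, 12), np.uint8)
        g[0, 0, 0] = g[5, 5, 5] = g[10, 10, 10] = 1
        with pytest.raises(ValueError, match="post-processing"):
            split_canals(VoxelMask(g, 0.4))
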