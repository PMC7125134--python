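"""Metric implementations versus brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from canalseg import metrics as met
from canalseg.curves import CurveLine
from canalseg.volume import VoxelMask


def brute_surface(mask):
    """Independent surface definition: mask voxel with an outside 6-neighbour."""
    g = mask.grid.astype(bool)
    out = []
    for idx in np.argwhere(g):
        for ax in range(3):
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if (n < 0).any() or (n >= np.array(g.shape)).any() or not g[tuple(n)]:
                    out.append(idx)
                    break
            else:
                continue
            break
    return np.array(out).reshape(-1, 3) * mask.spacing


def brute_assd(pred, truth):
    sp, st = brute_surface(pred), brute_surface(truth)
    d = cdist(st, sp)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(st) + len(sp))


def brute_rhd(pred, truth):
    sp, st = brute_surface(pred), brute_surface(truth)
    d = cdist(st, sp)
    return max(
        np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95)
    )


def random_mask(rng, shape, spacing=0.4, p=0.2):
    while True:
        g = (rng.random(shape) < p).astype(np.uint8)
        if g.any():
            return VoxelMask(g, spacing)


class TestConfusionAndOverlap:
    def test_counts_match_per_voxel_loop(self, rng):
        pred = random_mask(rng, (8, 8, 8))
        truth = random_mask(rng, (8, 8, 8))
        c = met.confusion(pred, truth)
        tp = fp = fn = tn = 0
        for idx in np.ndindex(8, 8, 8):
            p, t = bool(pred.grid[idx]), bool(truth.grid[idx])
            tp += p and t
            fp += p and not t
            fn += t and not p
            tn += not p and not t
        assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)
        assert c.total == 512

    def test_formula_values(self):
        c = met.ConfusionCounts(TP=5, FP=3, FN=2, TN=0)
        assert met.dsc(c) == pytest.approx(10 / 15)
        assert met.precision(c) == pytest.approx(5 / 8)
        assert met.recall(c) == pytest.approx(5 / 7)

    def test_perfect_and_disjoint(self):
        perfect = met.ConfusionCounts(TP=9, FP=0, FN=0, TN=1)
        assert met.dsc(perfect) == met.precision(perfect) == met.recall(perfect) == 1.0
        disjoint = met.ConfusionCounts(TP=0, FP=4, FN=6, TN=0)
        assert met.dsc(disjoint) == 0.0

    def test_undefined_marked_not_zero(self):
        assert np.isnan(met.dsc(met.ConfusionCounts(0, 0, 0, 8)))

    def test_dsc_harmonic_identity(self, rng):
        for _ in range(20):
            c = met.ConfusionCounts(*rng.integers(1, 50, size=4).tolist())
            pr, rc = met.precision(c), met.recall(c)
            assert met.dsc(c) == pytest.approx(2 * pr * rc / (pr + rc))


class TestSurface:
    def test_cube_surface_is_26_voxels(self):
        g = np.zeros((5, 5, 5), np.uint8)
        g[1:4, 1:4, 1:4] = 1
        surf = met.surface_indices(VoxelMask(g, 0.4))
        assert len(surf) == 26
        np.testing.assert_allclose(
            np.sort(surf, axis=0),
            np.sort(brute_surface(VoxelMask(g, 0.4)) / 0.4, axis=0),
            atol=1e-9,
        )

    def test_single_voxel_is_its_own_surface(self):
        g = np.zeros((3, 3, 3), np.uint8)
        g[1, 1, 1] = 1
        assert len(met.surface_indices(VoxelMask(g, 0.4))) == 1

    def test_thin_slab_is_all_surface(self):
        g = np.zeros((6, 6, 6), np.uint8)
        g[:, :, 2:4] = 1
        assert len(met.surface_indices(VoxelMask(g, 0.4))) == 6 * 6 * 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            met.surface_indices(VoxelMask(np.zeros((3, 3, 3), np.uint8), 0.4))


def parallel_plates(offset_voxels=2, spacing=0.4):
    a = np.zeros((10, 8, 8), np.uint8)
    b = np.zeros((10, 8, 8), np.uint8)
    a[3] = 1
    b[3 + offset_voxels] = 1
    return VoxelMask(a, spacing), VoxelMask(b, spacing)


class TestSurfaceDistances:
    def test_identical_masks_give_zero(self, rng):
        m = random_mask(rng, (6, 6, 6))
        assert met.assd(m, m) == 0.0
        assert met.rhd(m, m) == 0.0

    def test_offset_plates_closed_form(self):
        a, b = parallel_plates(2, 0.4)
        assert met.assd(a, b) == pytest.approx(0.8, abs=1e-12)
        assert met.rhd(a, b) == pytest.approx(0.8, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(25):
            shape = tuple(rng.integers(4, 13, 3))
            a, b = random_mask(rng, shape), random_mask(rng, shape)
            assert met.assd(a, b) == pytest.approx(brute_assd(a, b), abs=1e-9)
            assert met.rhd(a, b) == pytest.approx(brute_rhd(a, b), abs=1e-9)

    def test_symmetry(self, rng):
        a, b = random_mask(rng, (7, 7, 7)), random_mask(rng, (7, 7, 7))
        assert met.assd(a, b) == pytest.approx(met.assd(b, a), abs=1e-12)
        assert met.rhd(a, b) == pytest.approx(met.rhd(b, a), abs=1e-12)

    def test_scale_covariance(self, rng):
        a, b = random_mask(rng, (7, 7, 7)), random_mask(rng, (7, 7, 7))
        a2 = VoxelMask(a.grid, 0.8)
        b2 = VoxelMask(b.grid, 0.8)
        assert met.assd(a2, b2) == pytest.approx(2 * met.assd(a, b))
        assert met.rhd(a2, b2) == pytest.approx(2 * met.rhd(a, b))

    def test_empty_prediction_marked_failed(self, rng):
        empty = VoxelMask(np.zeros((5, 5, 5), np.uint8), 0.4)
        full = random_mask(rng, (5, 5, 5))
        assert np.isnan(met.assd(empty, full))
        assert np.isnan(met.rhd(empty, full))


class TestCurveDistance:
    def test_identical_curves_zero(self):
        c = CurveLine(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]))
        assert met.mcd(c, c) == 0.0

    def test_translated_parallel_lines(self):
        t = np.linspace(0, 10, 40)
        truth = CurveLine(np.column_stack([t, np.zeros_like(t), np.zeros_like(t)]))
        pred = CurveLine(truth.points + [0.4, 0.0, 0.0]).resample_step(0.01)
        # translation along the line: truth points land on the (densely
        # sampled) predicted line, apart from a small endpoint effect
        assert met.mcd(truth, pred) < 0.05
        pred_perp = CurveLine(truth.points + [0.0, 0.4, 0.0])
        assert met.mcd(truth, pred_perp) == pytest.approx(0.4, abs=1e-12)

    def test_matches_double_loop(self, rng):
        a = CurveLine(rng.random((15, 3)) * 10)
        b = CurveLine(rng.random((12, 3)) * 10)
        brute = np.mean(
            [min(np.linalg.norm(p - q) for q in b.points) for p in a.points]
        )
        assert met.mcd(a, b) == pytest.approx(brute, abs=1e-9)

    def test_intentionally_asymmetric(self):
        short = CurveLine(np.array([[0, 0, 0], [1, 0, 0.0]]))
        long = CurveLine(
            np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
        )
        assert met.mcd(short, long) != pytest.approx(met.mcd(long, short))


class TestSkeleton:
    def test_straight_tube_recovers_axis(self):
        from canalseg.annotation import tube_mask
        from canalseg.volume import Volume

        ref = Volume(np.zeros((110, 20, 20), np.float32), spacing=0.4)
        axis = CurveLine(np.array([[2.0, 4.0, 4.0], [42.0, 4.0, 4.0]]))
        mask = tube_mask(axis, 3.0, ref)
        curve = met.skeleton_curve(mask)
        d = np.abs(curve.points[:, 1:] - 4.0).max()
        assert d <= 0.4  # within one voxel of the true axis
        assert curve.length == pytest.approx(40.0, rel=0.10)

    def test_digital_line_is_fixed_point(self):
        g = np.zeros((10, 3, 3), np.uint8)
        g[1:9, 1, 1] = 1
        curve = met.skeleton_curve(VoxelMask(g, 0.4))
        assert len(curve) == 8
        np.testing.assert_allclose(curve.points[:, 1:], 0.4)

    def test_tube_has_two_endpoints(self, small_phantom):
        assert met.skeleton_endpoint_count(small_phantom.truth_masks[0]) == 2

    def test_multi_component_rejected(self):
        g = np.zeros((8, 8, 8), np.uint8)
        g[1, 1, 1] = 1
        g[6, 6, 6] = 1
        with pytest.raises(ValueError, match="components"):
            met.skeleton_curve(VoxelMask(g, 0.4))


class TestEvaluateCase:
    def test_perfect_prediction(self, small_phantom):
        mask = small_phantom.truth_masks[0]
        curve = met.skeleton_curve(mask)
        (rep,) = met.evaluate_case([mask], [mask], [curve])
        assert rep.dsc == 1.0
        assert rep.assd == 0.0 and rep.rhd == 0.0 and rep.mcd == 0.0
        assert not rep.failed

    def test_dilated_prediction_keeps_centerline(self, small_phantom):
        from scipy import ndimage

        truth = small_phantom.truth_masks[0]
        dilated = VoxelMask(
            ndimage.binary_dilation(truth.grid).astype(np.uint8), truth.spacing
        )
        (rep,) = met.evaluate_case(
            [dilated], [truth], [small_phantom.centerlines[0]]
        )
        assert rep.dsc < 1.0
        assert rep.mcd < 0.45  # dilation barely moves the centerline

    def test_empty_prediction_is_failure_row_not_crash(self, small_phantom):
        truth = small_phantom.truth_masks[0]
        (rep,) = met.evaluate_case([], [truth], [small_phantom.centerlines[0]])
        assert rep.failed
        assert np.isnan(rep.mcd) and np.isnan(rep.assd) and np.isnan(rep.rhd)
        assert rep.dsc == 0.0
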