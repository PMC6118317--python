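"""Unit and property tests for the per-well FMS pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from wellmotion import (
    SceneConfig,
    SegmentationParams,
    WellMasks,
    build_reference_mask,
    difference_mask,
    fractional_mobility,
    partition_movement,
    preprocess,
    quantify_well,
    remove_small_objects,
    simulate_well_pair,
)
from wellmotion.segmentation import _circular_mask

from conftest import small_scene


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.37)
        out = preprocess(img, blur_sigma=2.0)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_zero_sigma_is_identity(self):
        img = np.random.default_rng(0).uniform(size=(32, 32))
        assert preprocess(img, 0.0) is img

    def test_blur_conserves_interior_mass(self):
        # single bright interior pixel: Gaussian smoothing redistributes,
        # but does not create or destroy, intensity
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = preprocess(img, blur_sigma=2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=0.01)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((8, 8)), -1.0)


class TestReferenceMask:
    def test_blank_well_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        frame = preprocess(np.clip(0.7 + rng.normal(0, 0.01, (256, 256)), 0, 1), 1.0)
        mask = build_reference_mask(frame, SegmentationParams())
        assert mask.sum() < 50  # nothing segmentable in an empty well

    def test_covers_worms_not_background(self, well_pair):
        f1, _, truth = well_pair
        params = SegmentationParams()
        mask = build_reference_mask(preprocess(f1, params.blur_sigma), params)
        worms = truth.worm_mask_f1
        recall = (mask & worms).sum() / worms.sum()
        circle = _circular_mask(f1.shape, params.mask_radius_frac)
        bg = circle & ~worms
        fp = (mask & bg).sum() / bg.sum()
        assert recall >= 0.80
        assert fp <= 0.05

    def test_circular_mask_removes_rim(self):
        # a bright rim ring just inside the image border must not survive
        frame = np.full((128, 128), 0.05)
        yy, xx = np.ogrid[:128, :128]
        r = np.sqrt((yy - 63.5) ** 2 + (xx - 63.5) ** 2)
        frame[(r > 60) & (r < 64)] = 0.9
        params = SegmentationParams(mask_radius_frac=0.85)
        mask = build_reference_mask(preprocess(frame, 1.0), params)
        assert not mask[r > 0.9 * 64].any()


class TestRemoveSmallObjects:
    def test_size_rule(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2:4, 2:4] = True  # 4-px blob
        mask[10:30, 10:35] = True  # 500-px block
        out = remove_small_objects(mask, 50)
        assert not out[2:4, 2:4].any()
        assert out[10:30, 10:35].all()

    def test_zero_is_identity(self):
        mask = np.random.default_rng(1).uniform(size=(32, 32)) > 0.8
        np.testing.assert_array_equal(remove_small_objects(mask, 0), mask)

    def test_diagonal_touching_counts_as_one_object(self):
        # 8-connectivity: two diagonal 30-px blobs joined at a corner
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:8, 2:7] = True
        mask[8:14, 7:12] = True
        out = remove_small_objects(mask, 50)
        assert out.sum() == mask.sum()


class TestDifferenceMask:
    def test_identical_frames_zero(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        assert difference_mask(img, img, 0.01).sum() == 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(size=(2, 64, 64))
        np.testing.assert_array_equal(
            difference_mask(a, b, 0.05), difference_mask(b, a, 0.05)
        )

    def test_sub_threshold_noise_ignored(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(64, 64))
        b = a + rng.normal(0, 0.001, size=a.shape)
        assert difference_mask(a, b, 0.05).sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            difference_mask(np.zeros((4, 4)), np.zeros((4, 5)), 0.05)

    def test_displaced_worm_counted_twice(self):
        # disjoint displacement: the raw difference flags the worm at both
        # its old and new position — double the single-frame worm pixels
        scene = small_scene(n_worms=1, moving_fraction=1.0, noise_sigma=0.0, seed=5)
        f1, f2, truth = simulate_well_pair(scene)
        area = truth.worm_mask_f1.sum()
        diff = difference_mask(preprocess(f1, 1.0), preprocess(f2, 1.0), 0.01)
        old = truth.worm_masks_f1[0]
        new = truth.worm_masks_f2[0]
        assert (diff & old).sum() >= 0.95 * area  # old position flagged
        assert (diff & new).sum() >= 0.95 * area  # new position flagged too
        assert diff.sum() > 1.8 * area


class TestPartition:
    def test_saturated_diff(self):
        ref = np.random.default_rng(4).uniform(size=(16, 16)) > 0.5
        masks = partition_movement(np.ones((16, 16), dtype=bool), ref)
        np.testing.assert_array_equal(masks.moving, ref)
        assert masks.stationary.sum() == 0

    def test_empty_diff(self):
        ref = np.random.default_rng(5).uniform(size=(16, 16)) > 0.5
        masks = partition_movement(np.zeros((16, 16), dtype=bool), ref)
        assert masks.moving.sum() == 0
        np.testing.assert_array_equal(masks.stationary, ref)

    @settings(max_examples=50, deadline=None)
    @given(
        diff=hnp.arrays(bool, (16, 16)),
        ref=hnp.arrays(bool, (16, 16)),
    )
    def test_partition_matches_per_pixel_logic(self, diff, ref):
        # independent oracle: evaluate the set logic pixel by pixel
        masks = partition_movement(diff, ref)
        for idx in np.ndindex(16, 16):
            assert masks.moving[idx] == (diff[idx] and ref[idx])
            assert masks.stationary[idx] == (ref[idx] and not masks.moving[idx])
        masks.check()  # invariants: disjoint, union = reference

    @settings(max_examples=50, deadline=None)
    @given(
        diff=hnp.arrays(bool, (16, 16)),
        ref=hnp.arrays(bool, (16, 16)),
    )
    def test_conservation(self, diff, ref):
        masks = partition_movement(diff, ref)
        assert masks.moving.sum() + masks.stationary.sum() == masks.reference.sum()


class TestFractionalMobility:
    def test_all_moving_gives_one(self):
        ref = np.ones((16, 16), dtype=bool)
        masks = WellMasks(reference=ref, moving=ref.copy(), stationary=~ref)
        rec = fractional_mobility(masks)
        assert rec.valid and rec.fms == 1.0

    def test_none_moving_gives_zero(self):
        ref = np.ones((16, 16), dtype=bool)
        masks = WellMasks(reference=ref, moving=np.zeros_like(ref), stationary=ref.copy())
        rec = fractional_mobility(masks)
        assert rec.valid and rec.fms == 0.0

    def test_sparse_reference_invalid(self):
        ref = np.zeros((16, 16), dtype=bool)
        ref[0, :10] = True
        masks = WellMasks(reference=ref, moving=np.zeros_like(ref), stationary=ref.copy())
        rec = fractional_mobility(masks, min_worm_pixels=50)
        assert not rec.valid
        assert np.isnan(rec.fms)


class TestQuantifyWell:
    def test_identical_frames_score_zero(self, well_pair):
        f1, _, _ = well_pair
        rec = quantify_well(f1, f1)
        assert rec.valid
        assert rec.fms == 0.0

    def test_half_displaced_scene(self, well_pair):
        f1, f2, truth = well_pair
        rec = quantify_well(f1, f2)
        assert rec.valid
        assert rec.fms == pytest.approx(truth.true_moving_fraction, abs=0.1)

    def test_blank_pair_invalid(self):
        rng = np.random.default_rng(0)
        blank = np.clip(0.7 + rng.normal(0, 0.01, (256, 256)), 0, 1)
        blank2 = np.clip(0.7 + rng.normal(0, 0.01, (256, 256)), 0, 1)
        rec = quantify_well(blank, blank2)
        assert not rec.valid

    def test_fms_in_unit_interval_and_conserved(self):
        for seed in range(3):
            f1, f2, _ = simulate_well_pair(small_scene(seed=seed, moving_fraction=0.3))
            rec = quantify_well(f1, f2, keep_masks=True)
            assert 0.0 <= rec.fms <= 1.0
            m = rec.masks
            assert m.moving.sum() + m.stationary.sum() == m.reference.sum()

    def test_contrast_robustness(self, well_pair):
        f1, f2, _ = well_pair
        base = quantify_well(f1, f2).fms
        dimmed = quantify_well(0.8 * f1, 0.8 * f2).fms
        assert abs(base - dimmed) < 0.05

    def test_egg_filter_removes_eggs_from_reference(self):
        scene = small_scene(n_eggs=12, egg_radius_px=1.5, seed=21)
        f1, f2, _ = simulate_well_pair(scene)
        plain = quantify_well(f1, f2, SegmentationParams(), keep_masks=True)
        adult = quantify_well(
            f1, f2, SegmentationParams().with_adult_mode(100), keep_masks=True
        )
        assert adult.total_px < plain.total_px


class TestSegmentationParams:
    @pytest.mark.parametrize(
        "kw", [dict(adaptive_block=4), dict(adaptive_block=1),
               dict(mask_radius_frac=0.0), dict(mask_radius_frac=1.5),
               dict(diff_threshold=0.0), dict(blur_sigma=-1.0)]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SegmentationParams(**kw)

    def test_adult_mode_enables_size_filter(self):
        p = SegmentationParams().with_adult_mode()
        assert p.min_object_px > 0
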