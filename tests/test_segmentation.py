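"""Segmentation stage: Otsu, trinary/quaternary masks, GrabCut, colour correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoseq import simulate
from phenoseq.segmentation import (
    DEF_BG, DEF_FG, PROB_BG, PROB_FG,
    otsu_threshold, histogram_256, between_class_variance,
    channel_trinary_mask, combine_masks, grabcut_refine, segment_plant,
    color_correct, iou,
)


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class variance maximisation."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(len(hist)):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            v = 0.0
        else:
            mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / hist[: t + 1].sum()
            mu1 = (hist[t + 1:] * np.arange(t + 1, len(hist))).sum() / hist[t + 1:].sum()
            v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            hist = rng.integers(0, 50, size=256)
            hist[rng.integers(0, 256, size=5)] += rng.integers(100, 1000, size=5)
            if hist.sum() == 0:
                continue
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=8, max_size=64),
           st.integers(0, 200))
    def test_property_matches_exhaustive_search(self, counts, offset):
        hist = np.zeros(256, dtype=int)
        for i, c in enumerate(counts):
            hist[(offset + 3 * i) % 256] += c
        if hist.sum() == 0:
            hist[offset] = 1
        assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_two_delta_histogram_separates_the_masses(self):
        hist = np.zeros(256, dtype=int)
        hist[10] = 500
        hist[200] = 500
        t = otsu_threshold(hist)
        assert 10 <= t < 200

    def test_single_nonzero_bin_returns_that_level(self):
        hist = np.zeros(256, dtype=int)
        hist[137] = 10
        assert otsu_threshold(hist) == 137

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(256))

    def test_between_class_variance_consistent_with_threshold(self):
        rng = np.random.default_rng(3)
        hist = rng.integers(0, 100, 256)
        t = otsu_threshold(hist)
        vals = [between_class_variance(hist, u) for u in range(256)]
        assert between_class_variance(hist, t) == pytest.approx(max(vals))


class TestTrinaryMask:
    def test_constant_channel_yields_all_background(self):
        tri = channel_trinary_mask(np.full((20, 20), 7, dtype=np.uint8), "low")
        assert (tri == 0).all()

    def test_single_foreground_pixel_with_square_element(self):
        ch = np.full((9, 9), 200, dtype=np.uint8)
        ch[4, 4] = 10  # low side = foreground
        tri = channel_trinary_mask(ch, "low", selem=np.ones((3, 3), dtype=bool))
        assert tri[4, 4] == 2
        ring = [(r, c) for r in range(3, 6) for c in range(3, 6) if (r, c) != (4, 4)]
        assert all(tri[r, c] == 1 for r, c in ring)
        outside = tri.copy()
        outside[3:6, 3:6] = 0
        assert (outside == 0).all()

    def test_polarity_selects_foreground_side(self):
        ch = np.zeros((10, 10), dtype=np.uint8)
        ch[:, 5:] = 200
        tri_high = channel_trinary_mask(ch, "high", selem=np.ones((1, 1), dtype=bool))
        assert (tri_high[:, 5:] == 2).all() and (tri_high[:, :5] == 0).all()
        tri_low = channel_trinary_mask(ch, "low", selem=np.ones((1, 1), dtype=bool))
        assert (tri_low[:, :5] == 2).all() and (tri_low[:, 5:] == 0).all()


class TestCombineMasks:
    # the full 3x3 trinary-pair mapping
    CASES = {
        (0, 0): DEF_BG,
        (0, 1): PROB_BG, (1, 0): PROB_BG, (1, 1): PROB_BG,
        (0, 2): PROB_FG, (2, 0): PROB_FG, (1, 2): PROB_FG, (2, 1): PROB_FG,
        (2, 2): DEF_FG,
    }

    @pytest.mark.parametrize("pair,expected", sorted(CASES.items()))
    def test_mapping_cell(self, pair, expected):
        a = np.full((2, 2), pair[0], dtype=np.uint8)
        b = np.full((2, 2), pair[1], dtype=np.uint8)
        assert (combine_masks(a, b) == expected).all()

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, (30, 30))
        b = rng.integers(0, 3, (30, 30))
        assert (combine_masks(a, b) == combine_masks(b, a)).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_masks(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_invalid_level_raises(self):
        with pytest.raises(ValueError):
            combine_masks(np.full((2, 2), 3), np.zeros((2, 2)))


def _disc_scene(canvas=96, radius=20):
    """Green disc on brown noise, with its quaternary seed and truth mask."""
    rng = np.random.default_rng(5)
    img = np.clip(rng.normal([115, 85, 60], 8, (canvas, canvas, 3)), 0, 255)
    yy, xx = np.mgrid[:canvas, :canvas]
    disc = (yy - canvas // 2) ** 2 + (xx - canvas // 2) ** 2 <= radius ** 2
    img[disc] = np.clip(rng.normal([60, 130, 55], 8, (disc.sum(), 3)), 0, 255)
    img = img.astype(np.uint8)
    seed = np.full((canvas, canvas), PROB_BG, dtype=np.uint8)
    inner = (yy - canvas // 2) ** 2 + (xx - canvas // 2) ** 2 <= (radius - 6) ** 2
    near = (yy - canvas // 2) ** 2 + (xx - canvas // 2) ** 2 <= (radius + 6) ** 2
    seed[near] = PROB_FG
    seed[inner] = DEF_FG
    seed[0:4, :] = DEF_BG
    return img, seed, disc


class TestGrabCut:
    def test_disc_recovered_with_high_overlap(self):
        img, seed, truth = _disc_scene()
        mask = grabcut_refine(img, seed)
        assert iou(mask, truth) >= 0.9

    def test_definite_seed_levels_are_never_flipped(self):
        img, seed, _ = _disc_scene()
        mask = grabcut_refine(img, seed)
        assert mask[seed == DEF_FG].all()
        assert not mask[seed == DEF_BG].any()

    def test_output_is_boolean_of_input_shape(self):
        img, seed, _ = _disc_scene(canvas=72, radius=15)
        mask = grabcut_refine(img, seed)
        assert mask.dtype == bool and mask.shape == img.shape[:2]

    def test_seed_without_foreground_evidence_raises(self):
        img, _, _ = _disc_scene()
        with pytest.raises(ValueError):
            grabcut_refine(img, np.zeros(img.shape[:2], dtype=np.uint8))


class TestSegmentPlant:
    def test_mid_growth_rosette_high_iou(self, easy_panel):
        rgb, truth = simulate.render_frame(easy_panel[2], day=15, canvas_size=128, seed=9)
        assert iou(segment_plant(rgb), truth) >= 0.8

    def test_plant_free_frame_yields_empty_mask(self, easy_panel):
        rgb, truth = simulate.render_frame(easy_panel[0], day=0, canvas_size=128,
                                           seed=4, germination_offset=3)
        assert truth.sum() == 0
        assert segment_plant(rgb).sum() == 0

    def test_segmented_area_tracks_growth(self, easy_panel):
        areas = []
        for day in (6, 10, 14, 18):
            rgb, _ = simulate.render_frame(easy_panel[0], day=day, canvas_size=128, seed=2)
            areas.append(segment_plant(rgb).sum())
        for a, b in zip(areas, areas[1:]):
            assert b >= 0.9 * a

    def test_non_rgb_input_raises(self):
        with pytest.raises(ValueError):
            segment_plant(np.zeros((10, 10), dtype=np.uint8))


class TestColorCorrect:
    def test_identity_patches_leave_image_unchanged(self):
        rng = np.random.default_rng(1)
        patches = rng.integers(0, 255, (6, 3)).astype(float)
        img = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
        out = color_correct(img, patches, patches)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_recovers_known_channel_halving(self):
        rng = np.random.default_rng(2)
        ref = rng.integers(20, 240, (8, 3)).astype(float)
        obs = ref / 2.0
        img = (ref[:4] / 2.0).reshape(2, 2, 3)
        out = color_correct(img, obs, ref)
        assert np.allclose(out, ref[:4].reshape(2, 2, 3), atol=1e-6)

    def test_too_few_patches_raise(self):
        p = np.random.default_rng(0).integers(0, 255, (3, 3)).astype(float)
        with pytest.raises(ValueError):
            color_correct(np.zeros((2, 2, 3)), p, p)

    def test_rank_deficient_patches_raise(self):
        p = np.tile([[10.0, 20.0, 30.0]], (5, 1))
        with pytest.raises(ValueError):
            color_correct(np.zeros((2, 2, 3)), p, p)
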