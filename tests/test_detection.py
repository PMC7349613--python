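"""HSV conversion, threshold masks, candidate extraction, quality gates."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowtag.detection import (
    NOISE_REMOVAL,
    TAG_DETECTION,
    HsvThresholds,
    TagCandidate,
    extract_tag_candidates,
    hsv_mask,
    initial_noise_filter,
    rms_contrast,
    standard_image_filter,
    to_hsv_unit,
)
from cowtag.synthetic import TagRenderSpec, render_tag


class TestToHsvUnit:
    def test_pure_red(self):
        hsv = to_hsv_unit(np.array([[[255, 0, 0]]], dtype=np.uint8))
        np.testing.assert_allclose(hsv[0, 0], [0.0, 1.0, 1.0], atol=1e-6)

    def test_white_is_achromatic(self):
        hsv = to_hsv_unit(np.array([[[255, 255, 255]]], dtype=np.uint8))
        assert hsv[0, 0, 1] == 0.0
        assert hsv[0, 0, 2] == 1.0

    def test_agrees_with_colorsys(self):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 256, size=(1000, 1, 3), dtype=np.uint8)
        hsv = to_hsv_unit(pixels)
        for i in range(1000):
            r, g, b = (pixels[i, 0] / 255.0).tolist()
            expected = colorsys.rgb_to_hsv(r, g, b)
            np.testing.assert_allclose(hsv[i, 0], expected, atol=1e-6)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            to_hsv_unit(np.zeros((4, 4), dtype=np.uint8))


class TestHsvMask:
    def test_inside_detection_ranges(self):
        hsv = np.array([[[0.15, 0.30, 0.50]]])
        assert hsv_mask(hsv, TAG_DETECTION)[0, 0]

    def test_hue_above_range(self):
        hsv = np.array([[[0.30, 0.30, 0.50]]])
        assert not hsv_mask(hsv, TAG_DETECTION)[0, 0]

    def test_closed_boundaries(self):
        hsv = np.array([[[0.082, 0.072, 0.0]]])
        assert hsv_mask(hsv, TAG_DETECTION)[0, 0]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            HsvThresholds(0.5, 0.2, 0.0, 1.0, 0.0, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_widening_is_monotone(self, seed):
        """Widening any threshold interval never removes mask pixels."""
        rng = np.random.default_rng(seed)
        hsv = rng.random((12, 12, 3))
        lo = rng.random(3) * 0.5
        hi = lo + rng.random(3) * 0.5
        t = HsvThresholds(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
        wide = HsvThresholds(
            max(0, lo[0] - 0.1), min(1, hi[0] + 0.1),
            max(0, lo[1] - 0.1), min(1, hi[1] + 0.1),
            max(0, lo[2] - 0.1), min(1, hi[2] + 0.1),
        )
        assert not (hsv_mask(hsv, t) & ~hsv_mask(hsv, wide)).any()


class TestExtractCandidates:
    def test_rendered_tag_found(self, clean_renders):
        hits = 0
        for _, img, gt in clean_renders[:20]:
            cands = extract_tag_candidates(img)
            assert len(cands) == 1
            hits += cands[0].source_box.iou(gt.tag_box) >= 0.5
        assert hits == 20

    def test_all_black_crop(self):
        crop = np.zeros((50, 50, 3), dtype=np.uint8)
        assert extract_tag_candidates(crop) == []

    def test_small_speck_suppressed(self):
        """A tag plus a yellow speck below the minimum area yields one
        candidate."""
        img, gt = render_tag(TagRenderSpec(tag_id="1249", seed=0))
        img = img.copy()
        img[2:8, 2:8] = [160, 150, 80]  # 36 px < min area 100
        cands = extract_tag_candidates(img)
        assert len(cands) == 1
        assert cands[0].source_box.iou(gt.tag_box) >= 0.5

    def test_stall_position_validation(self):
        with pytest.raises(ValueError):
            TagCandidate(np.zeros((4, 4, 3), dtype=np.uint8), None, 0, 9)


def _density_oracle(image, thresholds):
    hsv = to_hsv_unit(image)
    count = 0
    for row in hsv.reshape(-1, 3):
        h, s, v = row
        if (thresholds.h_lo <= h <= thresholds.h_hi
                and thresholds.s_lo <= s <= thresholds.s_hi
                and thresholds.v_lo <= v <= thresholds.v_hi):
            count += 1
    return count


class TestFilters:
    def test_density_equals_per_pixel_oracle(self):
        img, _ = render_tag(TagRenderSpec(tag_id="0647", canvas_size=(64, 64),
                                          seed=2))
        cand = extract_tag_candidates(img)[0]
        report = initial_noise_filter(cand)
        assert report.pixel_density == _density_oracle(cand.image, NOISE_REMOVAL)

    def test_initial_bounds_inclusive(self):
        """400 and 2700 pass; 399 and 2701 fail (synthetic mask counts)."""
        base = np.zeros((60, 60, 3), dtype=np.uint8)

        def with_density(n):
            img = base.copy()
            ys, xs = np.unravel_index(np.arange(n), (60, 60))
            img[ys, xs] = [150, 140, 80]  # inside the tight ranges
            cand = TagCandidate(img, None, 0, 1)
            return initial_noise_filter(cand)

        assert not with_density(399).passed
        assert with_density(400).passed
        assert with_density(2700).passed
        assert not with_density(2701).passed

    def test_all_zero_mask(self):
        cand = TagCandidate(np.zeros((20, 20, 3), dtype=np.uint8), None, 0, 1)
        report = initial_noise_filter(cand)
        assert report.pixel_density == 0 and not report.passed

    def test_standard_density_strictly_greater(self):
        """Contrast in range but density exactly at the threshold fails."""
        rng = np.random.default_rng(0)
        img = (rng.random((200, 200, 3)) * 255).astype(np.uint8)
        cand = TagCandidate(img, None, 0, 1)
        report, _ = standard_image_filter(cand, min_density=10**9)
        assert not report.passed

    def test_uniform_gray_contrast_zero(self):
        img = np.full((50, 50, 3), 128, dtype=np.uint8)
        cand = TagCandidate(img, None, 0, 1)
        report, _ = standard_image_filter(cand)
        assert report.contrast < 0.01 and not report.passed

    def test_rms_contrast_definition(self):
        gray = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert rms_contrast(gray) == pytest.approx(0.5)

    def test_clean_small_tags_pass_both_gates(self):
        """Clean renders sized for the native-density gate pass both
        filters >= 90% of the time."""
        passed = 0
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            spec = TagRenderSpec(tag_id=f"{rng.integers(0, 10000):04d}",
                                 canvas_size=(88, 88), seed=2000 + i)
            img, _ = render_tag(spec)
            cands = extract_tag_candidates(img)
            if len(cands) != 1:
                continue
            if (initial_noise_filter(cands[0]).passed
                    and standard_image_filter(cands[0])[0].passed):
                passed += 1
        assert passed >= 45

    def test_heavy_blur_rejected(self):
        """Renders with blur sigma >= 6 fail the standard gate >= 80%."""
        rejected = 0
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            spec = TagRenderSpec(tag_id=f"{rng.integers(0, 10000):04d}",
                                 canvas_size=(88, 88), blur_sigma=6.0,
                                 seed=2000 + i)
            img, _ = render_tag(spec)
            cands = extract_tag_candidates(img)
            if not cands:
                rejected += 1
                continue
            if not standard_image_filter(cands[0])[0].passed:
                rejected += 1
        assert rejected >= 40
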