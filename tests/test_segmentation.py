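"""Projection profiles, valley points, border removal, barcode and digit
segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowtag.errors import InputError, SegmentationError, SegmentRejected
from cowtag.segmentation import (
    BarcodeArea,
    detect_barcode_area,
    digit_area_start,
    prepare_digit,
    preprocess_tag,
    projection,
    remove_borders,
    resolve_digit_objects,
    segment_columns,
    segment_digits,
    valley_points,
)
from cowtag.synthetic import CELL_HSV, PRINT_HSV, TagRenderSpec, render_tag

from skimage.color import hsv2rgb


def _cell_rgb():
    return (hsv2rgb(np.array([[list(CELL_HSV)]]))[0, 0] * 255).astype(np.uint8)


def _print_rgb():
    return (hsv2rgb(np.array([[list(PRINT_HSV)]]))[0, 0] * 255).astype(np.uint8)


class TestPreprocess:
    def test_print_is_foreground_on_clean_render(self, clean_renders):
        """Foreground covers the ground-truth digit cells with recall
        >= 0.9 (the cells are printed, hence binarize to foreground)."""
        _, img, gt = clean_renders[0]
        tb = gt.tag_box
        binary = preprocess_tag(img[tb.y0 : tb.y1, tb.x0 : tb.x1])
        for box in gt.digit_boxes:
            cell = binary[box.y0 - tb.y0 : box.y1 - tb.y0,
                          box.x0 - tb.x0 : box.x1 - tb.x0]
            assert cell.mean() >= 0.9

    def test_uniform_input_all_zero(self):
        img = np.full((40, 40, 3), 127, dtype=np.uint8)
        assert not preprocess_tag(img).any()

    def test_shape_preserved(self):
        img = np.zeros((33, 57, 3), dtype=np.uint8)
        assert preprocess_tag(img).shape == (33, 57)


class TestProjection:
    def test_identity_pattern_rows(self):
        eye = np.eye(3, dtype=bool)
        assert projection(eye, "rows").values.tolist() == [1, 1, 1]

    def test_all_ones_cols(self):
        ones = np.ones((4, 5), dtype=bool)
        assert projection(ones, "cols").values.tolist() == [4] * 5

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        binary = rng.random((20, 20)) < 0.5
        rows = projection(binary, "rows").values
        cols = projection(binary, "cols").values
        for i in range(20):
            assert rows[i] == sum(bool(binary[i, j]) for j in range(20))
            assert cols[i] == sum(bool(binary[j, i]) for j in range(20))


class TestValleyPoints:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5, 3, 6, 2, 8], [1, 3]),
            ([1, 2, 3, 4], []),
            ([4, 4, 4], []),
            ([5, 0, 0, 0, 5], [2]),  # flat run collapses to its centre
            ([5, 2, 2, 5, 1, 9], [1, 4]),
        ],
    )
    def test_known_profiles(self, values, expected):
        assert valley_points(np.array(values)) == expected

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            valley_points(np.array([1, 2]))

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_definition_oracle(self, seed):
        """Strictly-lower-than-both-neighbours definition, on profiles
        without ties between neighbours."""
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(rng.integers(3, 60)))
        expected = [
            i
            for i in range(1, len(values) - 1)
            if values[i] < values[i - 1] and values[i] < values[i + 1]
        ]
        assert valley_points(values) == expected


class TestRemoveBorders:
    def test_clean_render_trims_to_content_box(self, clean_renders):
        """Trimmed crop equals the printed-content box within 2 px/edge."""
        for _, img, gt in clean_renders[:10]:
            tb = gt.tag_box
            crop = img[tb.y0 : tb.y1, tb.x0 : tb.x1]
            _, _, box = remove_borders(preprocess_tag(crop), crop)
            content = gt.content_box.shift(-tb.x0, -tb.y0)
            assert abs(box.x0 - content.x0) <= 2
            assert abs(box.y0 - content.y0) <= 2
            assert abs(box.x1 - content.x1) <= 2
            assert abs(box.y1 - content.y1) <= 2

    def test_no_low_projection_margins_unchanged(self):
        """An image whose edge rows/columns already exceed the projection
        thresholds is returned untrimmed."""
        rgb = np.full((30, 30, 3), 200, dtype=np.uint8)
        rgb[:, :10] = 30   # dark print spanning full height at both edges
        rgb[:, -10:] = 30
        binary = preprocess_tag(rgb)
        out_b, out_rgb, box = remove_borders(binary, rgb)
        assert box == (0, 0, 30, 30)

    def test_all_zero_binary_rejected(self):
        with pytest.raises(SegmentationError):
            remove_borders(np.zeros((20, 20), dtype=bool),
                           np.zeros((20, 20, 3), dtype=np.uint8))


class TestBarcodeArea:
    def test_clean_render_band_end(self, clean_renders):
        """Detected band end within 3 rows of the rendered band bottom."""
        hits = 0
        for _, img, gt in clean_renders[:10]:
            tb = gt.tag_box
            crop = img[tb.y0 : tb.y1, tb.x0 : tb.x1]
            binary, _, box = remove_borders(preprocess_tag(crop), crop)
            bc = detect_barcode_area(binary)
            assert bc is not None
            true_end = gt.barcode_rows[1] - tb.y0 - box.y0
            # the detected end is the valley centre in the band-digit gap
            hits += abs(bc.end_row - true_end) <= 3
        assert hits >= 9

    def test_no_valleys_absent(self):
        assert detect_barcode_area(np.ones((40, 40), dtype=bool)) is None

    def test_synthetic_candidate_sequence(self):
        """Candidates at h/8, h/3, h/2: the band ends at the first one
        deeper than h/4 (h/3) and starts at the prior one (h/8)."""
        h, w = 80, 60
        binary = np.ones((h, w), dtype=bool)
        for row in (h // 8, h // 3, h // 2):
            binary[row, :] = False  # projection 0 < w/2, isolated valley
        bc = detect_barcode_area(binary)
        assert bc == BarcodeArea(h // 8, h // 3)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            BarcodeArea(10, 10)


class TestDigitAreaStart:
    def test_barcode_end_taken_when_conditions_hold(self):
        """Band (10, 40) in a 100-row image with a wide object in the
        band: remaining 60 > 1.7 x 30, so the start is the band end."""
        binary = np.zeros((100, 80), dtype=bool)
        binary[12:38, 5:75] = True  # one object, 70 px wide > 40
        assert digit_area_start(binary, BarcodeArea(10, 40)) == 40

    def test_fallback_when_too_little_remains(self):
        """Band (10, 60): remaining 40 <= 1.7 x 50, fallback path."""
        binary = np.zeros((100, 80), dtype=bool)
        binary[12:58, 5:75] = True
        start = digit_area_start(binary, BarcodeArea(10, 60))
        assert start != 60  # fallback produced a profile-based row

    def test_fallback_picks_minimum_projection_point(self):
        """No barcode: among {estimate, nearest valley, previous, next}
        the row with the smallest projection value wins."""
        h, w = 100, 60
        binary = np.ones((h, w), dtype=bool)
        binary[30, :] = False          # deep valley far above the estimate
        binary[44, :40] = False        # shallow valley near 0.45 x 100
        binary[60, :10] = False        # shallower valley below
        start = digit_area_start(binary, None)
        assert start == 30

    def test_occluded_barcode_render_still_segments(self):
        """With the band wiped out, the fallback start stays above the
        digit cells and the digit stage still yields 4 crops."""
        spec = TagRenderSpec(tag_id="5208", seed=12)
        img, gt = render_tag(spec)
        tb = gt.tag_box
        crop = img[tb.y0 : tb.y1, tb.x0 : tb.x1].copy()
        # paint the barcode band over with field colour
        crop[gt.barcode_rows[0] - tb.y0 : gt.barcode_rows[1] - tb.y0, 5:-5] = (
            crop[-5, 5]
        )
        binary, _, box = remove_borders(preprocess_tag(crop), crop)
        start = digit_area_start(binary, detect_barcode_area(binary))
        digit_top = gt.digit_boxes[0].y0 - tb.y0 - box.y0
        assert start <= digit_top + 2
        segs = segment_digits(crop)
        assert sum(len(s.crops) for s in segs) == 4


class TestSegmentColumns:
    def test_clean_renders_give_four_spans(self, clean_renders):
        """>= 90% of 50 clean renders yield exactly 4 spans, each holding
        one ground-truth digit centre, with column IoU >= 0.7."""
        good = 0
        for _, img, gt in clean_renders:
            tb = gt.tag_box
            crop = img[tb.y0 : tb.y1, tb.x0 : tb.x1]
            try:
                binary, _, box = remove_borders(preprocess_tag(crop), crop)
                start = digit_area_start(binary, detect_barcode_area(binary))
                spans = segment_columns(binary[start:])
            except SegmentationError:
                continue
            if len(spans) != 4:
                continue
            ok = True
            for span, dbox in zip(spans, gt.digit_boxes):
                lo = dbox.x0 - tb.x0 - box.x0
                hi = dbox.x1 - tb.x0 - box.x0
                centre = (lo + hi) / 2
                inter = max(0, min(span[1], hi) - max(span[0], lo))
                union = (span[1] - span[0]) + (hi - lo) - inter
                if not (span[0] <= centre < span[1] and inter / union >= 0.7):
                    ok = False
            good += ok
        assert good >= 45

    def test_blank_crop_rejected(self):
        with pytest.raises(SegmentationError):
            segment_columns(np.zeros((40, 60), dtype=bool))

    def test_mini_digit_never_yields_a_fifth_crop(self, clean_renders):
        """The trailing mini digit is dropped (narrow span or failed
        object criteria): the final digit count stays 4."""
        for _, img, gt in clean_renders[:10]:
            tb = gt.tag_box
            segs = segment_digits(img[tb.y0 : tb.y1, tb.x0 : tb.x1])
            assert sum(len(s.crops) for s in segs) == 4


class TestResolveDigitObjects:
    def _segment(self, objects, h=60, w=30):
        """Build a field-coloured segment with printed rectangles."""
        img = np.full((h, w, 3), 170, dtype=np.uint8)
        for (x0, y0, x1, y1) in objects:
            img[y0:y1, x0:x1] = _cell_rgb()
        return img

    def test_single_qualifying_object(self):
        img = self._segment([(5, 5, 25, 55)])  # w 20 < h 50, h 50 > 40
        crops = resolve_digit_objects(img)
        assert len(crops) == 1
        assert crops[0].shape[:2] == (50, 20)

    def test_mini_digit_eliminated(self):
        """A short object (mini digit) fails the two-thirds-height rule;
        only the full digit comes back."""
        img = self._segment([(2, 5, 14, 55), (18, 20, 26, 35)])
        crops = resolve_digit_objects(img)
        assert len(crops) == 1
        assert crops[0].shape[1] == 12

    def test_wide_object_is_noise(self):
        """Wider-than-tall objects (border fragments) never qualify."""
        img = self._segment([(2, 50, 28, 56)])
        with pytest.raises(SegmentRejected):
            resolve_digit_objects(img)

    def test_touching_digits_split_at_average_line(self):
        img = self._segment([(2, 5, 13, 55), (16, 5, 27, 55)], w=30)
        crops = resolve_digit_objects(img)
        assert len(crops) == 2
        # split midway between x=13 and x=16 -> 14; widths 14 and 16
        assert crops[0].shape[1] == 14
        assert crops[1].shape[1] == 16

    def test_empty_segment_rejected(self):
        with pytest.raises(SegmentRejected):
            resolve_digit_objects(np.zeros((0, 0, 3), dtype=np.uint8))


class TestPrepareDigit:
    def test_output_shape_and_binarity(self):
        rng = np.random.default_rng(0)
        crop = (rng.random((37, 19, 3)) * 255).astype(np.uint8)
        out = prepare_digit(crop)
        assert out.shape == (64, 32)
        assert set(np.unique(out)) <= {0, 1}

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        crop = (rng.random((50, 24, 3)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(prepare_digit(crop), prepare_digit(crop))

    def test_polarity_consistent(self):
        """The darker printed region becomes foreground (complement is
        applied once, on the grayscale)."""
        img = np.full((40, 20, 3), 200, dtype=np.uint8)
        img[10:30, 5:15] = 30
        out = prepare_digit(img)
        assert out[32, 16] == 1  # centre of the dark patch
        assert out[2, 2] == 0

    def test_empty_crop_rejected(self):
        with pytest.raises(InputError):
            prepare_digit(np.zeros((0, 5, 3), dtype=np.uint8))
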