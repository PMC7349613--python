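"""Digit isolation on a normalized tag crop.

The recognition front end works on projection profiles of a binarized
crop (grayscale -> invert -> histogram-equalize -> Otsu binarize, so
foreground = printed ink).  Steps:

1. *Border removal* — empty margin rows are trimmed while their row
   projection stays below half the image width; the RGB crop is re-cut,
   re-preprocessed, and margin columns are trimmed while their column
   projection stays below two-thirds of the (new) image height.
2. *Barcode detection* — row-projection valley points whose value is
   below half the width are candidate band boundaries; the first one
   deeper than a quarter of the height ends the band.
3. *Digit-area start* — the barcode end starts the digit area when
   enough height remains (1.7x the band height) and the band holds an
   object wider than half the image; otherwise a fallback picks the
   lowest-projection row near 0.45x the image height.
4. *Column segmentation* — column-projection valleys (shallower than
   half the height) plus the image edges are cut points; points that
   bound only gaps narrower than one-sixth of the width are dropped.
5. *Object determination* — inside each span, dark objects
   (gray < 150) taller than two-thirds of the span height and narrower
   than tall are digits; mini digits and noise fail these criteria, and
   touching digit pairs are split at the midline between objects.

Valley points use strict inequality against both neighbours; a flat run
flanked by higher values counts once, at its centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import resize

from .errors import InputError, SegmentationError, SegmentRejected
from .geometry import Box

__all__ = [
    "ProjectionProfile",
    "BarcodeArea",
    "DigitSegment",
    "preprocess_tag",
    "projection",
    "valley_points",
    "remove_borders",
    "detect_barcode_area",
    "digit_area_start",
    "segment_columns",
    "resolve_digit_objects",
    "prepare_digit",
    "segment_digits",
]


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-row or per-column foreground pixel counts."""

    values: np.ndarray  # 1-D int array
    axis: Literal["rows", "cols"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if self.values.ndim != 1:
            raise ValueError("profile must be 1-D")
        if self.axis not in ("rows", "cols"):
            raise ValueError(f"axis must be 'rows' or 'cols', got {self.axis!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BarcodeArea:
    start_row: int
    end_row: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_row < self.end_row:
            raise ValueError("need 0 <= start_row < end_row")

    @property
    def height(self) -> int:
        return self.end_row - self.start_row


@dataclass(frozen=True)
class DigitSegment:
    """One column span of the digit area and its resolved digit crops."""

    col_span: tuple[int, int]
    crops: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.col_span[1] <= self.col_span[0]:
            raise ValueError("empty column span")
        for c in self.crops:
            if c.size == 0:
                raise ValueError("empty digit crop")


def preprocess_tag(tag_crop: np.ndarray) -> np.ndarray:
    """Binarize a tag crop so printed ink is foreground.

    Grayscale -> invert -> histogram equalization -> Otsu threshold.
    A uniform input yields an all-zero binary.
    """
    gray = rgb2gray(np.asarray(tag_crop)) if tag_crop.ndim == 3 else (
        np.asarray(tag_crop, dtype=np.float64) / 255.0
    )
    inverted = 1.0 - gray
    if np.ptp(inverted) < 1e-9:
        return np.zeros(inverted.shape, dtype=bool)
    # Equalization is monotone, so binarizing the equalized image at the
    # mapped threshold equals binarizing the inverted grayscale directly;
    # the threshold is selected on the pre-equalization histogram, whose
    # ink/field bimodality equalization would flatten away.
    return inverted > threshold_otsu(inverted)


def projection(binary: np.ndarray, axis: Literal["rows", "cols"]) -> ProjectionProfile:
    """Foreground count per row (axis='rows') or per column ('cols')."""
    binary = np.asarray(binary, dtype=bool)
    values = binary.sum(axis=1) if axis == "rows" else binary.sum(axis=0)
    return ProjectionProfile(values, axis)


def valley_points(p: ProjectionProfile | np.ndarray) -> list[int]:
    """Indices strictly lower than both neighbours; a flat run flanked by
    higher values counts once at its centre.  Endpoints never qualify."""
    values = p.values if isinstance(p, ProjectionProfile) else np.asarray(p)
    if len(values) < 3:
        raise InputError("profile must have at least 3 entries")
    # collapse runs of equal values
    starts = [0]
    for i in range(1, len(values)):
        if values[i] != values[starts[-1]]:
            starts.append(i)
    out = []
    for k in range(1, len(starts) - 1):
        s = starts[k]
        e = starts[k + 1] - 1  # inclusive end of the run
        if values[s] < values[starts[k - 1]] and values[s] < values[starts[k + 1]]:
            out.append((s + e) // 2)
    return out


def remove_borders(
    binary: np.ndarray, rgb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, Box]:
    """Trim empty margins; returns (binary, rgb, box-in-input-coords).

    Rows are trimmed edge-inward while their projection is below half
    the width; the RGB is re-cut and re-preprocessed before columns are
    trimmed while their projection is below two-thirds of the height.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0:
        raise SegmentationError("empty input")
    h, w = binary.shape
    rows = projection(binary, "rows").values
    r0 = 0
    while r0 < h and rows[r0] < w / 2:
        r0 += 1
    r1 = h
    while r1 > r0 and rows[r1 - 1] < w / 2:
        r1 -= 1
    if r0 >= r1:
        raise SegmentationError("all rows trimmed as border")
    rgb_rows = rgb[r0:r1]
    binary2 = preprocess_tag(rgb_rows)
    h2, w2 = binary2.shape
    cols = projection(binary2, "cols").values
    c0 = 0
    while c0 < w2 and cols[c0] < 2 * h2 / 3:
        c0 += 1
    c1 = w2
    while c1 > c0 and cols[c1 - 1] < 2 * h2 / 3:
        c1 -= 1
    if c0 >= c1:
        raise SegmentationError("all columns trimmed as border")
    return binary2[:, c0:c1], rgb_rows[:, c0:c1], Box(c0, r0, c1, r1)


def detect_barcode_area(
    binary: np.ndarray, min_row_frac: float = 0.25
) -> Optional[BarcodeArea]:
    """Locate the barcode band from row-projection valley points.

    Candidate points are valleys whose projection value is below half
    the width; the band ends at the first candidate deeper than
    ``min_row_frac`` of the height and starts at the previous candidate
    (row 0 when the end is the first candidate).  Returns ``None`` when
    no candidate qualifies.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if h < 3:
        return None
    rows = projection(binary, "rows").values
    candidates = [i for i in valley_points(rows) if rows[i] < w / 2]
    end_row = None
    end_idx = None
    for idx, i in enumerate(candidates):
        if i > h * min_row_frac:
            end_row, end_idx = i, idx
            break
    if end_row is None:
        return None
    start_row = candidates[end_idx - 1] if end_idx > 0 else 0
    return BarcodeArea(start_row, end_row)


def _widest_object(binary: np.ndarray) -> int:
    widest = 0
    for region in regionprops(label(binary)):
        _, c0, _, c1 = region.bbox
        widest = max(widest, c1 - c0)
    return widest


def digit_area_start(
    binary: np.ndarray,
    barcode: Optional[BarcodeArea],
    height_ratio: float = 1.7,
    object_width_frac: float = 0.5,
    start_fraction: float = 0.45,
    start_fraction_axis: Literal["height", "width"] = "height",
) -> int:
    """Row where the digit area begins.

    The barcode end row is used when enough height remains below it
    (``height_ratio`` times the band height) and the band contains an
    object wider than ``object_width_frac`` of the width.  Otherwise a
    fallback estimates ``start_fraction`` of the image extent
    (``start_fraction_axis`` selects height or width as the reference),
    and returns whichever of {estimate, nearest valley, previous valley,
    next valley} has the smallest projection value.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if barcode is not None:
        remaining = h - barcode.end_row
        band = binary[barcode.start_row : barcode.end_row]
        if (
            remaining > height_ratio * barcode.height
            and _widest_object(band) > object_width_frac * w
        ):
            return barcode.end_row
    base = h if start_fraction_axis == "height" else w
    est = min(h - 1, max(0, int(round(start_fraction * base))))
    rows = projection(binary, "rows").values
    try:
        valleys = valley_points(rows)
    except InputError:
        valleys = []
    if not valleys:
        return est
    nearest_idx = int(np.argmin([abs(v - est) for v in valleys]))
    pool = [est, valleys[nearest_idx]]
    if nearest_idx > 0:
        pool.append(valleys[nearest_idx - 1])
    if nearest_idx < len(valleys) - 1:
        pool.append(valleys[nearest_idx + 1])
    # smallest projection value wins; ties break toward the estimate
    pool.sort(key=lambda r: (rows[r], abs(r - est)))
    return pool[0]


def segment_columns(
    digit_binary: np.ndarray,
    min_width_frac: float = 1.0 / 6.0,
) -> list[tuple[int, int]]:
    """Cut the digit area into column spans at projection valleys.

    Valleys deeper than half the image height are discarded; the image
    edges join the remaining points.  A point survives only if it bounds
    at least one gap wider than ``min_width_frac`` of the width, and the
    spans between surviving points are returned (ideally four).
    """
    digit_binary = np.asarray(digit_binary, dtype=bool)
    h, w = digit_binary.shape
    if h < 1 or w < 3:
        raise SegmentationError("digit area too small")
    if not digit_binary.any():
        raise SegmentationError("blank digit area")
    cols = projection(digit_binary, "cols").values
    valleys = [v for v in valley_points(cols) if cols[v] <= h / 2]
    points = [0] + valleys + [w]
    min_width = min_width_frac * w
    gaps = [points[i + 1] - points[i] for i in range(len(points) - 1)]
    surviving = []
    for i, pt in enumerate(points):
        left_wide = i > 0 and gaps[i - 1] > min_width
        right_wide = i < len(gaps) and gaps[i] > min_width
        if left_wide or right_wide:
            surviving.append(pt)
    if len(surviving) < 2:
        raise SegmentationError("fewer than two surviving cut points")
    return [
        (surviving[i], surviving[i + 1])
        for i in range(len(surviving) - 1)
        if surviving[i + 1] - surviving[i] > min_width
    ]


def resolve_digit_objects(
    segment_rgb: np.ndarray,
    gray_threshold: int = 150,
    height_frac: float = 2.0 / 3.0,
    max_crops: int = 2,
) -> list[np.ndarray]:
    """Extract 1-2 digit crops from one column span of the RGB crop.

    Foreground is gray < ``gray_threshold`` (8-bit scale).  An object is
    a digit when its width is less than its height and its height
    exceeds ``height_frac`` of the span height.  One digit: its bounding
    box is cropped from the RGB.  Several (touching digits): a split
    line midway between adjacent objects separates the crops.  None:
    the span is rejected.
    """
    segment_rgb = np.asarray(segment_rgb)
    if segment_rgb.size == 0:
        raise SegmentRejected("empty segment")
    h, w = segment_rgb.shape[:2]
    gray = rgb2gray(segment_rgb) * 255.0 if segment_rgb.ndim == 3 else segment_rgb
    fg = gray < gray_threshold
    digits: list[Box] = []
    for region in regionprops(label(fg)):
        r0, c0, r1, c1 = region.bbox
        ow, oh = c1 - c0, r1 - r0
        if ow < oh and oh > height_frac * h:
            digits.append(Box(c0, r0, c1, r1))
    if not digits:
        raise SegmentRejected("no qualifying digit object in span")
    digits.sort(key=lambda b: b.x0)
    digits = digits[:max_crops]
    if len(digits) == 1:
        b = digits[0]
        return [segment_rgb[b.y0 : b.y1, b.x0 : b.x1]]
    # average split lines midway between adjacent objects
    cuts = [0]
    for a, b in zip(digits, digits[1:]):
        cuts.append((a.x1 + b.x0) // 2)
    cuts.append(w)
    crops = []
    for i, b in enumerate(digits):
        crops.append(segment_rgb[b.y0 : b.y1, cuts[i] : cuts[i + 1]])
    return crops


def prepare_digit(digit_rgb: np.ndarray, shape: tuple[int, int] = (64, 32)) -> np.ndarray:
    """Normalize one digit crop to a 64 x 32 binary image (uint8 {0,1}).

    Grayscale -> complement -> histogram equalization -> Otsu
    binarization -> resize.  Deterministic.
    """
    digit_rgb = np.asarray(digit_rgb)
    if digit_rgb.size == 0:
        raise InputError("empty digit crop")
    gray = rgb2gray(digit_rgb) if digit_rgb.ndim == 3 else (
        np.asarray(digit_rgb, dtype=np.float64) / 255.0
    )
    comp = 1.0 - gray
    if np.ptp(comp) < 1e-9:
        binary = np.zeros(comp.shape, dtype=float)
    else:
        # same monotone-equalization argument as in preprocess_tag; the
        # threshold is estimated on the central region so that margin
        # pixels leaking in from outside the digit cannot dominate the
        # histogram, then applied to the whole crop
        h, w = comp.shape
        my, mx = max(1, int(0.15 * h)), max(1, int(0.15 * w))
        center = comp[my : h - my, mx : w - mx]
        if center.size == 0 or np.ptp(center) < 1e-9:
            center = comp
        binary = (comp > threshold_otsu(center)).astype(float)
    out = resize(binary, shape, order=1, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def _write_debug(debug_dir, name: str, image: np.ndarray) -> None:
    import imageio.v3 as iio
    from pathlib import Path

    path = Path(debug_dir)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(path / f"{name}.png", arr)


def segment_digits(
    tag_crop: np.ndarray,
    gray_threshold: int = 150,
    min_width_frac: float = 1.0 / 6.0,
    start_fraction: float = 0.45,
    start_fraction_axis: Literal["height", "width"] = "height",
    debug_dir=None,
) -> list[DigitSegment]:
    """Full segmentation chain: normalized tag crop -> digit segments.

    Convenience orchestration of preprocess, border removal, barcode
    detection, digit-area start, column cuts and object determination.
    Spans with no qualifying object are dropped; raises
    :class:`SegmentationError` when nothing survives.  When ``debug_dir``
    is given, per-stage PNGs (binary, border-removed crop, digit area,
    digit crops) are written there for visual inspection.
    """
    binary = preprocess_tag(tag_crop)
    if debug_dir:
        _write_debug(debug_dir, "00_binary", binary)
    binary, rgb, _ = remove_borders(binary, np.asarray(tag_crop))
    if debug_dir:
        _write_debug(debug_dir, "01_border_removed", rgb)
    barcode = detect_barcode_area(binary)
    start = digit_area_start(
        binary, barcode,
        start_fraction=start_fraction,
        start_fraction_axis=start_fraction_axis,
    )
    digit_binary = binary[start:]
    digit_rgb = rgb[start:]
    if digit_binary.shape[0] < 3:
        raise SegmentationError("no rows below the digit-area start")
    if debug_dir:
        _write_debug(debug_dir, "02_digit_area", digit_rgb)
    segments: list[DigitSegment] = []
    for c0, c1 in segment_columns(digit_binary, min_width_frac):
        try:
            crops = resolve_digit_objects(
                digit_rgb[:, c0:c1], gray_threshold=gray_threshold
            )
        except SegmentRejected:
            continue
        segments.append(DigitSegment((c0, c1), tuple(crops)))
    if not segments:
        raise SegmentationError("no digit segments survived")
    if debug_dir:
        for i, seg in enumerate(segments):
            for j, crop in enumerate(seg.crops):
                _write_debug(debug_dir, f"03_digit_{i}_{j}", crop)
    return segments
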