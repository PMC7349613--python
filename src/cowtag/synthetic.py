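"""Ground-truthed synthetic ear-tag imagery.

No public dataset of cow head images with annotated ear tags exists, so
every downstream stage is exercised on rendered imagery.  A rendered tag
emulates the yellow plastic tag format: a printed frame, a barcode band
across the top, four large work-number digits, and a trailing mini
digit.  The renderer also produces multi-stall feeding-station scenes
(dark head proxies with an attached tag, five stalls per camera view),
labelled digit training sets, and noisy recognition-string streams for
the confirmation and temporal-decision stages.

Colour and print design constraints (all verified by tests):

* the tag field, the dark print and the digit cells all fall inside the
  wide HSV detection ranges, so a tag forms one connected mask component;
* only the field falls inside the tight noise-removal ranges (the print
  hue sits below that range), so density gates count the yellow field
  alone, as they would on a real tag;
* digits are printed in reverse video: each work-number digit (and the
  mini digit) is a light glyph punched out of a solid dark cell.  Solid
  cells give the digit band a column-projection profile with deep
  valleys only at the true inter-digit gaps — glyph-interior columns
  can never dip below the half-height valley-discard threshold, which
  real tag typefaces achieve with very heavy stroke weights;
* cell grayscale ~34 and punched-glyph grayscale ~72 both sit well
  below the fixed digit binarisation threshold (gray < 150), so object
  determination sees each cell as one solid digit object, while the
  per-digit Otsu separates glyph from cell for classification;
* background and head-proxy colours fall outside both HSV presets.

All geometry is parameterised by the tag side length T; ground truth is
exact by construction.  Every random decision flows through one
``numpy.random.Generator`` seeded per call, so identical specs render
byte-identical images.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.color import hsv2rgb
from skimage.filters import gaussian
from skimage.transform import resize, rotate
from PIL import ImageFont

from .geometry import Box

__all__ = [
    "TagRenderSpec",
    "TagGroundTruth",
    "SceneSpec",
    "StallTruth",
    "render_tag",
    "render_scene",
    "default_layout",
    "generate_digit_dataset",
    "simulate_recognition_stream",
    "glyph_bitmap",
    "FONT_NAMES",
    "image_digest",
    "write_tag_png",
]

_TAG_RE = re.compile(r"^[0-9]{4}$")

# Two open sans-serif faces shipped with matplotlib; rasterised once and
# cached.  Variety between faces hardens the digit classifier.
FONT_NAMES = ("DejaVuSans-Bold.ttf", "DejaVuSansMono-Bold.ttf")

# Palette (HSV for tag colours, RGB floats otherwise).
FIELD_SV = (0.22, 0.655)
INK_HSV = (0.10, 0.45, 0.16)  # dark orange print: inside the wide
# detection ranges (coverage) but below the tight range's H>=0.128, so
# quality-gate pixel density counts only the yellow field, as on real tags
CELL_HSV = INK_HSV  # digit cells share the print colour
# Punched glyph: dark-gray print (~gray 68).  Groups with the cell under
# both the tag-stage Otsu binarisation and the fixed gray<150 threshold
# (solid cells for projections and object determination) while the
# per-digit Otsu still separates glyph from cell for classification.
PRINT_HSV = (0.10, 0.40, 0.33)
BACKGROUND_RGB = (0.645, 0.645, 0.645)  # station gray: matches the field's
# grayscale so padded crop margins join the field cluster under Otsu,
# but achromatic, hence outside both HSV presets
FUR_RGB = (0.33, 0.20, 0.13)  # fur brown for occlusion blobs, outside both presets
HEAD_RGB = (0.295, 0.295, 0.295)  # achromatic dark gray
NOISE_SIGMA = 1.5 / 255.0

# Tag geometry as fractions of the tag side length T.
CONTENT = (0.07, 0.93)  # frame outer bounds, both axes
FRAME_FRAC = 0.022
BARCODE_Y = (0.10, 0.32)
BARCODE_X = (0.11, 0.89)
DIGIT_Y = (0.37, 0.88)
DIGIT_X0, DIGIT_PITCH, DIGIT_W = 0.11, 0.16, 0.12
MINI_X = (0.74, 0.80)
MINI_Y = (0.50, 0.66)


def _font_path(name: str) -> str:
    import matplotlib

    return str(Path(matplotlib.__file__).parent / "mpl-data" / "fonts" / "ttf" / name)


_GLYPH_CACHE: dict[tuple[int, int], np.ndarray] = {}


def glyph_bitmap(digit: int, font_index: int = 0) -> np.ndarray:
    """Anti-aliased ink mask of a digit glyph, cropped to its ink bounds,
    values in [0, 1].  Rasterised once at a large point size and cached."""
    if not 0 <= digit <= 9:
        raise ValueError(f"digit must be 0..9, got {digit}")
    key = (digit, font_index)
    if key not in _GLYPH_CACHE:
        font = ImageFont.truetype(_font_path(FONT_NAMES[font_index]), 128)
        mask = font.getmask(str(digit), mode="L")
        arr = np.asarray(mask, dtype=np.float64).reshape(mask.size[1], mask.size[0])
        arr /= 255.0
        rows = np.flatnonzero(arr.max(axis=1) > 0.1)
        cols = np.flatnonzero(arr.max(axis=0) > 0.1)
        _GLYPH_CACHE[key] = arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()
    return _GLYPH_CACHE[key]


@dataclass(frozen=True)
class TagRenderSpec:
    """Parameters for one rendered ear tag."""

    tag_id: str
    canvas_size: tuple[int, int] = (160, 160)  # (height, width) px
    skew_deg: float = 0.0
    blur_sigma: float = 0.0
    occlusion_frac: float = 0.0
    base_hue: float = 0.15
    seed: int = 0
    tag_frac: float = 0.73  # tag side length as fraction of min canvas dim

    def __post_init__(self) -> None:
        if not _TAG_RE.match(self.tag_id):
            raise ValueError(f"tag_id must be 4 digits, got {self.tag_id!r}")
        if min(self.canvas_size) < 64:
            raise ValueError("canvas_size must be at least (64, 64)")
        if not -20.0 <= self.skew_deg <= 20.0:
            raise ValueError("skew_deg must lie in [-20, 20]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0.0 <= self.occlusion_frac < 1.0:
            raise ValueError("occlusion_frac must lie in [0, 1)")


@dataclass(frozen=True)
class TagGroundTruth:
    """Exact layout of a rendered tag, in unrotated canvas coordinates.

    For skewed renders the boxes describe the pre-rotation layout; tests
    of box geometry use unskewed renders and tests of skew use only
    ``skew_deg``.
    """

    digit_boxes: tuple[Box, Box, Box, Box]
    mini_digit_box: Box
    barcode_rows: tuple[int, int]
    skew_deg: float
    tag_box: Box
    content_box: Box

    def __post_init__(self) -> None:
        xs = [b.x0 for b in self.digit_boxes]
        if xs != sorted(xs):
            raise ValueError("digit boxes must be ordered left to right")
        for a, b in zip(self.digit_boxes, self.digit_boxes[1:]):
            if a.x1 > b.x0:
                raise ValueError("digit boxes must be disjoint")
        if self.barcode_rows[0] >= self.barcode_rows[1]:
            raise ValueError("barcode start row must precede end row")

    def to_json(self) -> str:
        d = {
            "digit_boxes": [list(b) for b in self.digit_boxes],
            "mini_digit_box": list(self.mini_digit_box),
            "barcode_rows": list(self.barcode_rows),
            "skew_deg": self.skew_deg,
            "tag_box": list(self.tag_box),
            "content_box": list(self.content_box),
        }
        return json.dumps(d, indent=1)


def _paste_digit_cell(canvas: np.ndarray, box: Box, digit: int, font_index: int,
                      cell: np.ndarray, glyph_color: np.ndarray,
                      inset: int | None = None) -> None:
    """Reverse-video digit: solid dark cell, glyph punched out in the
    light colour, kept ``inset`` px away from the cell edges so the cell
    stays one connected object."""
    if inset is None:
        inset = max(1, round(0.12 * box.width))
    region = canvas[box.y0 : box.y1, box.x0 : box.x1]
    region[:] = cell
    gh = max(1, box.height - 2 * inset)
    gw = max(1, box.width - 2 * inset)
    glyph = glyph_bitmap(digit, font_index)
    alpha = resize(glyph, (gh, gw), order=1, anti_aliasing=True)
    alpha = np.clip(alpha, 0.0, 1.0)[..., None]
    inner = region[inset : inset + gh, inset : inset + gw]
    inner[:] = inner * (1 - alpha) + glyph_color * alpha


def _render_tag_patch(
    tag_id: str, T: int, rng: np.random.Generator, base_hue: float,
    font_index: Optional[int] = None,
) -> tuple[np.ndarray, dict]:
    """Render a T x T tag patch (float RGB) plus layout in patch coords."""
    field = hsv2rgb(np.array([[[base_hue, *FIELD_SV]]]))[0, 0]
    ink = hsv2rgb(np.array([[INK_HSV]]))[0].reshape(3)
    patch = np.empty((T, T, 3), dtype=np.float64)
    patch[:] = field

    def px(f: float) -> int:
        return int(round(f * T))

    c0, c1 = px(CONTENT[0]), px(CONTENT[1])
    t = max(2, px(FRAME_FRAC))
    # printed frame
    patch[c0 : c0 + t, c0:c1] = ink
    patch[c1 - t : c1, c0:c1] = ink
    patch[c0:c1, c0 : c0 + t] = ink
    patch[c0:c1, c1 - t : c1] = ink
    # barcode band: vertical bars hanging below the frame top
    bar_y0, bar_y1 = c0 + t, px(BARCODE_Y[1])
    x = px(BARCODE_X[0])
    x_end = px(BARCODE_X[1])
    bar_w = max(1, px(0.018))
    while x + bar_w <= x_end:
        patch[bar_y0:bar_y1, x : x + bar_w] = ink
        x += bar_w + max(1, px(0.012)) * int(rng.integers(1, 3))
    # four work-number digits in reverse-video cells
    if font_index is None:
        font_index = int(rng.integers(0, len(FONT_NAMES)))
    cell = hsv2rgb(np.array([[CELL_HSV]]))[0].reshape(3)
    glyph_print = hsv2rgb(np.array([[PRINT_HSV]]))[0].reshape(3)
    dy0, dy1 = px(DIGIT_Y[0]), px(DIGIT_Y[1])
    digit_boxes = []
    for i, ch in enumerate(tag_id):
        x0 = px(DIGIT_X0 + i * DIGIT_PITCH)
        box = Box(x0, dy0, x0 + px(DIGIT_W), dy1)
        _paste_digit_cell(patch, box, int(ch), font_index, cell, glyph_print)
        digit_boxes.append(box)
    # trailing mini digit (checksum-style), smaller cell
    mini_box = Box(px(MINI_X[0]), px(MINI_Y[0]), px(MINI_X[1]), px(MINI_Y[1]))
    mini_digit = int(rng.integers(0, 10))
    _paste_digit_cell(patch, mini_box, mini_digit, font_index, cell,
                      glyph_print, inset=1)
    layout = {
        "digit_boxes": digit_boxes,
        "mini_digit_box": mini_box,
        "barcode_rows": (bar_y0, bar_y1),
        "content_box": Box(c0, c0, c1, c1),
    }
    return patch, layout


def _occlude(canvas: np.ndarray, tag_box: Box, frac: float,
             rng: np.random.Generator) -> None:
    """Cover up to ``frac`` of the tag area with opaque fur-coloured blobs."""
    if frac <= 0:
        return
    target = frac * tag_box.area
    covered = np.zeros((tag_box.height, tag_box.width), dtype=bool)
    fur = np.asarray(FUR_RGB)
    yy, xx = np.mgrid[0 : tag_box.height, 0 : tag_box.width]
    for _ in range(64):
        if covered.sum() >= target:
            break
        cy = rng.uniform(0, tag_box.height)
        cx = rng.uniform(0, tag_box.width)
        ry = rng.uniform(0.05, 0.18) * tag_box.height
        rx = rng.uniform(0.05, 0.18) * tag_box.width
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        allowed = target - covered.sum()
        if np.count_nonzero(blob & ~covered) > allowed:
            continue
        covered |= blob
        region = canvas[tag_box.y0 : tag_box.y1, tag_box.x0 : tag_box.x1]
        region[blob] = fur * rng.uniform(0.85, 1.15)


def render_tag(spec: TagRenderSpec) -> tuple[np.ndarray, TagGroundTruth]:
    """Render one ear tag on a fur-coloured canvas.

    Returns the RGB uint8 image and exact ground truth.  Deterministic:
    the same spec always yields a byte-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.canvas_size
    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = np.asarray(BACKGROUND_RGB)
    T = int(round(spec.tag_frac * min(H, W)))
    x0, y0 = (W - T) // 2, (H - T) // 2
    patch, layout = _render_tag_patch(spec.tag_id, T, rng, spec.base_hue)
    canvas[y0 : y0 + T, x0 : x0 + T] = patch
    tag_box = Box(x0, y0, x0 + T, y0 + T)
    _occlude(canvas, tag_box, spec.occlusion_frac, rng)
    if spec.skew_deg != 0.0:
        # rotate(angle=-s) gives a baseline whose measured incline is +s
        canvas = rotate(canvas, -spec.skew_deg, mode="constant",
                        cval=0.0, order=1)
        fell_outside = canvas.sum(axis=2) == 0.0
        canvas[fell_outside] = np.asarray(BACKGROUND_RGB)
    if spec.blur_sigma > 0:
        canvas = gaussian(canvas, sigma=spec.blur_sigma, channel_axis=-1)
    canvas += rng.normal(0.0, NOISE_SIGMA, canvas.shape)
    image = np.clip(canvas * 255.0, 0, 255).astype(np.uint8)
    truth = TagGroundTruth(
        digit_boxes=tuple(b.shift(x0, y0) for b in layout["digit_boxes"]),
        mini_digit_box=layout["mini_digit_box"].shift(x0, y0),
        barcode_rows=(layout["barcode_rows"][0] + y0, layout["barcode_rows"][1] + y0),
        skew_deg=spec.skew_deg,
        tag_box=tag_box,
        content_box=layout["content_box"].shift(x0, y0),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Scenes


def default_layout(frame_size: tuple[int, int] = (340, 960),
                   stall_count: int = 5) -> tuple[Box, ...]:
    """Evenly split the frame into ``stall_count`` disjoint stall regions."""
    H, W = frame_size
    pitch = W // stall_count
    return tuple(
        Box(i * pitch + 2, 0, (i + 1) * pitch - 2, H) for i in range(stall_count)
    )


@dataclass(frozen=True)
class SceneSpec:
    """A feeding-station camera view: up to five stalls, each optionally
    occupied by a cow (identified by its ear-tag work number)."""

    occupancy: tuple[Optional[str], ...]
    layout: tuple[Box, ...] = field(default_factory=default_layout)
    frame_size: tuple[int, int] = (340, 960)
    seed: int = 0
    stall_count: int = 5

    def __post_init__(self) -> None:
        if len(self.occupancy) != self.stall_count:
            raise ValueError("occupancy length must equal stall_count")
        if len(self.layout) != self.stall_count:
            raise ValueError("layout must have one region per stall")
        boxes = sorted(self.layout, key=lambda b: b.x0)
        for a, b in zip(boxes, boxes[1:]):
            if a.x1 > b.x0:
                raise ValueError("stall regions must be disjoint")
        for tag in self.occupancy:
            if tag is not None and not _TAG_RE.match(tag):
                raise ValueError(f"bad tag_id {tag!r}")


@dataclass(frozen=True)
class StallTruth:
    position: int  # 1-based stall position
    tag_id: str
    head_box: Box  # covers the head proxy and the attached tag
    tag_box: Box


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, list[StallTruth]]:
    """Render one camera frame: dark head proxies with attached tags."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_size
    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = np.asarray(BACKGROUND_RGB) * 0.97
    truths: list[StallTruth] = []
    yy_all, xx_all = np.mgrid[0:H, 0:W]
    for idx, tag_id in enumerate(spec.occupancy):
        if tag_id is None:
            continue
        region = spec.layout[idx]
        cx = region.x0 + region.width * rng.uniform(0.40, 0.55)
        cy = H * rng.uniform(0.32, 0.42)
        ry, rx = H * 0.22, min(region.width * 0.28, 60)
        ellipse = ((yy_all - cy) / ry) ** 2 + ((xx_all - cx) / rx) ** 2 <= 1.0
        canvas[ellipse] = np.asarray(HEAD_RGB) * rng.uniform(0.9, 1.1)
        # ear tag hangs below and to the side of the head proxy
        T = int(rng.integers(56, 67))
        tx = int(np.clip(cx + rx * rng.choice((-1, 1)) * 0.7 - T / 2,
                         region.x0 + 2, region.x1 - T - 2))
        ty = int(np.clip(cy + ry * 0.55, 2, H - T - 2))
        patch, _ = _render_tag_patch(tag_id, T, rng, 0.15)
        canvas[ty : ty + T, tx : tx + T] = patch
        tag_box = Box(tx, ty, tx + T, ty + T)
        ey0, ey1 = int(cy - ry), int(cy + ry)
        ex0, ex1 = int(cx - rx), int(cx + rx)
        head_box = Box(
            min(ex0, tag_box.x0) - 3, min(ey0, tag_box.y0) - 3,
            max(ex1, tag_box.x1) + 3, max(ey1, tag_box.y1) + 3,
        )
        head_box = Box(max(0, head_box.x0), max(0, head_box.y0),
                       min(W, head_box.x1), min(H, head_box.y1))
        truths.append(StallTruth(idx + 1, tag_id, head_box, tag_box))
    canvas += rng.normal(0.0, NOISE_SIGMA, canvas.shape)
    image = np.clip(canvas * 255.0, 0, 255).astype(np.uint8)
    return image, truths


# ---------------------------------------------------------------------------
# Digit training data


def _digit_preprocess(crop: np.ndarray) -> np.ndarray:
    from .segmentation import prepare_digit

    return prepare_digit(crop)


def generate_digit_dataset(
    n_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 64 x 32 binary digit images, ``n_per_class`` per digit.

    Each sample emulates one digit-cell crop as the segmentation stage
    produces it: a reverse-video cell (light glyph punched out of a dark
    cell) rendered from one of the two bundled faces at a random size
    and aspect, randomly translated, lightly rotated, blurred and
    noised, then passed through the recognition preprocessing chain
    (grayscale, complement, equalise, binarise, resize to 64 x 32).
    Returns ``(images, labels)`` with images uint8 in {0, 1}, shuffled.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    glyph_print = hsv2rgb(np.array([[PRINT_HSV]]))[0].reshape(3)
    cell = hsv2rgb(np.array([[CELL_HSV]]))[0].reshape(3)
    images = np.empty((10 * n_per_class, 64, 32), dtype=np.uint8)
    labels = np.empty(10 * n_per_class, dtype=np.int64)
    order = rng.permutation(10 * n_per_class)
    k = 0
    for digit in range(10):
        for _ in range(n_per_class):
            font_index = int(rng.integers(0, len(FONT_NAMES)))
            ch = int(rng.integers(40, 72))  # cell height px
            cw = int(ch * rng.uniform(0.40, 0.58))
            inset_y = int(rng.integers(1, 5))
            inset_x = int(rng.integers(1, 4))
            crop = np.empty((ch, cw, 3))
            crop[:] = cell * rng.uniform(0.85, 1.15)
            gh = max(1, ch - 2 * inset_y)
            gw = max(1, cw - 2 * inset_x)
            alpha = resize(glyph_bitmap(digit, font_index), (gh, gw),
                           order=1, anti_aliasing=True)
            alpha = np.clip(alpha, 0.0, 1.0)[..., None]
            inner = crop[inset_y : inset_y + gh, inset_x : inset_x + gw]
            inner[:] = inner * (1 - alpha) + glyph_print * rng.uniform(0.9, 1.1) * alpha
            if rng.random() < 0.5:
                crop = rotate(crop, rng.uniform(-4, 4), mode="edge", order=1)
            sigma = rng.uniform(0.0, 1.1)
            if sigma > 0.05:
                crop = gaussian(crop, sigma=sigma, channel_axis=-1)
            crop += rng.normal(0.0, 2 * NOISE_SIGMA, crop.shape)
            crop8 = np.clip(crop * 255, 0, 255).astype(np.uint8)
            images[order[k]] = _digit_preprocess(crop8)
            labels[order[k]] = digit
            k += 1
    return images, labels


# ---------------------------------------------------------------------------
# Recognition-string streams


def simulate_recognition_stream(
    true_tags: dict[int, str],
    error_model: dict[str, float],
    n_frames: int,
    seed: int = 0,
) -> list[dict[int, Optional[str]]]:
    """Per-frame, per-stall recognized strings derived from the true tags.

    ``error_model`` keys (all probabilities, default 0): ``p_miss_frame``
    (no reading emitted for the stall that frame), ``p_drop_digit`` and
    ``p_substitute`` (applied independently per digit), ``p_insert``
    (a spurious digit inserted, tested once per gap between/around
    digits).  Absent readings are ``None``.
    """
    for key, p in error_model.items():
        if key not in {"p_drop_digit", "p_substitute", "p_insert", "p_miss_frame"}:
            raise ValueError(f"unknown error model key {key!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{key} must be a probability, got {p}")
    p_drop = error_model.get("p_drop_digit", 0.0)
    p_sub = error_model.get("p_substitute", 0.0)
    p_ins = error_model.get("p_insert", 0.0)
    p_miss = error_model.get("p_miss_frame", 0.0)
    rng = np.random.default_rng(seed)
    frames: list[dict[int, Optional[str]]] = []
    digits = "0123456789"
    for _ in range(n_frames):
        readings: dict[int, Optional[str]] = {}
        for stall in sorted(true_tags):
            tag = true_tags[stall]
            if rng.random() < p_miss:
                readings[stall] = None
                continue
            out = []
            for ch in tag:
                if rng.random() < p_ins:
                    out.append(digits[rng.integers(0, 10)])
                if rng.random() < p_drop:
                    continue
                if rng.random() < p_sub:
                    out.append(digits[rng.integers(0, 10)])
                else:
                    out.append(ch)
            if rng.random() < p_ins:
                out.append(digits[rng.integers(0, 10)])
            readings[stall] = "".join(out)
        frames.append(readings)
    return frames


# ---------------------------------------------------------------------------
# Artifact output


def image_digest(image: np.ndarray) -> str:
    """SHA-256 of an image's bytes plus shape, for determinism checks."""
    h = hashlib.sha256()
    h.update(str(image.shape).encode())
    h.update(np.ascontiguousarray(image).tobytes())
    return h.hexdigest()


def write_tag_png(
    image: np.ndarray, truth: TagGroundTruth, path: str | Path
) -> tuple[Path, Path]:
    """Write a rendered tag as PNG plus a JSON ground-truth sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(truth.to_json())
    return path, sidecar
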