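"""Ear-tag candidate extraction and quality filtering.

A head crop is searched for the yellow tag by thresholding in HSV space.
Two threshold presets are used: a wide one for locating candidate tag
regions (``TAG_DETECTION``) and a tighter one (``NOISE_REMOVAL``) whose
binary mask drives the two quality gates:

* *initial filter* — the mask's foreground pixel count ("pixel density")
  at the candidate's native size must lie in [400, 2700]; rejects specks
  and oversized yellow areas (feed, mud);
* *standard filter* — after resizing the crop to 200 x 200, the density
  must exceed 15,500 and the RMS contrast of the grayscale crop must lie
  in [0.17, 0.65]; rejects blurred and fur-covered tags.

"Contrast" here is root-mean-square contrast: the standard deviation of
grayscale intensities scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import label, regionprops
from skimage.morphology import closing, footprint_rectangle
from skimage.transform import resize

from .geometry import Box

__all__ = [
    "HsvThresholds",
    "TagCandidate",
    "FilterReport",
    "TAG_DETECTION",
    "NOISE_REMOVAL",
    "to_hsv_unit",
    "hsv_mask",
    "extract_tag_candidates",
    "initial_noise_filter",
    "standard_image_filter",
]


@dataclass(frozen=True)
class HsvThresholds:
    """Closed per-channel intervals on unit-scaled HSV."""

    h_lo: float
    h_hi: float
    s_lo: float
    s_hi: float
    v_lo: float
    v_hi: float

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.h_lo, self.h_hi, "h"),
            (self.s_lo, self.s_hi, "s"),
            (self.v_lo, self.v_hi, "v"),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid {name} interval [{lo}, {hi}]")


#: Wide preset used to locate candidate tag regions in a head crop.
TAG_DETECTION = HsvThresholds(0.082, 0.263, 0.072, 0.559, 0.0, 1.0)

#: Tight preset whose mask defines pixel density for both quality gates.
NOISE_REMOVAL = HsvThresholds(0.128, 0.345, 0.067, 0.582, 0.0, 0.667)


@dataclass(frozen=True)
class TagCandidate:
    """A cropped sub-image hypothesised to be an ear tag."""

    image: np.ndarray  # RGB uint8 crop
    source_box: Box  # in head-crop coordinates
    frame_id: int = 0
    stall_position: int = 1

    def __post_init__(self) -> None:
        if self.image.size == 0:
            raise ValueError("empty candidate crop")
        if not 1 <= self.stall_position <= 5:
            raise ValueError(f"stall_position must be 1..5, got {self.stall_position}")


@dataclass(frozen=True)
class FilterReport:
    stage: str  # "initial" | "standard"
    pixel_density: int
    passed: bool
    contrast: Optional[float] = None  # standard stage only


def to_hsv_unit(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV with all channels in [0, 1].

    Hue follows the usual convention (red = 0, yellow ~ 1/6).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return rgb2hsv(image)


def hsv_mask(hsv: np.ndarray, t: HsvThresholds) -> np.ndarray:
    """Boolean mask: pixel is set iff all three HSV channels fall inside
    their closed threshold intervals."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return (
        (t.h_lo <= h) & (h <= t.h_hi)
        & (t.s_lo <= s) & (s <= t.s_hi)
        & (t.v_lo <= v) & (v <= t.v_hi)
    )


def extract_tag_candidates(
    head_crop: np.ndarray,
    frame_id: int = 0,
    stall_position: int = 1,
    thresholds: HsvThresholds = TAG_DETECTION,
    min_area: int = 100,
    pad: int = 4,
) -> list[TagCandidate]:
    """Connected components of the detection mask become candidates.

    A 3x3 morphological closing bridges small mask holes before
    labelling; components below ``min_area`` are dropped.  Each candidate
    is the component's bounding box (padded by ``pad`` px, clamped to the
    crop) taken from the original RGB image.
    """
    head_crop = np.asarray(head_crop)
    if head_crop.size == 0:
        raise ValueError("empty head crop")
    mask = hsv_mask(to_hsv_unit(head_crop), thresholds)
    mask = closing(mask, footprint_rectangle((3, 3)))
    out: list[TagCandidate] = []
    h, w = mask.shape
    for region in regionprops(label(mask)):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        box = Box(max(0, c0 - pad), max(0, r0 - pad), min(w, c1 + pad), min(h, r1 + pad))
        crop = head_crop[box.y0 : box.y1, box.x0 : box.x1]
        out.append(TagCandidate(crop, box, frame_id, stall_position))
    out.sort(key=lambda c: c.source_box.x0)
    return out


def _density(image: np.ndarray, thresholds: HsvThresholds) -> int:
    return int(hsv_mask(to_hsv_unit(image), thresholds).sum())


def initial_noise_filter(
    c: TagCandidate,
    thresholds: HsvThresholds = NOISE_REMOVAL,
    density_range: tuple[int, int] = (400, 2700),
) -> FilterReport:
    """Pixel-density gate at the candidate's native size (bounds inclusive)."""
    density = _density(c.image, thresholds)
    lo, hi = density_range
    return FilterReport("initial", density, lo <= density <= hi)


def rms_contrast(gray: np.ndarray) -> float:
    """Standard deviation of intensities scaled to [0, 1]."""
    return float(np.std(gray))


def resize_standard(image: np.ndarray, size: int = 200) -> np.ndarray:
    """Resize a candidate crop to the standard size, preserving uint8 range."""
    out = resize(image, (size, size), order=1, preserve_range=True, anti_aliasing=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def standard_image_filter(
    c: TagCandidate,
    thresholds: HsvThresholds = NOISE_REMOVAL,
    contrast_range: tuple[float, float] = (0.17, 0.65),
    min_density: int = 15500,
    size: int = 200,
) -> tuple[FilterReport, np.ndarray]:
    """Blur / fur-cover gate on the 200 x 200 resized crop.

    Passes iff contrast lies in ``contrast_range`` (inclusive) and mask
    density strictly exceeds ``min_density``.  Returns the report and the
    resized crop so the pipeline can reuse it.
    """
    std = resize_standard(c.image, size)
    density = _density(std, thresholds)
    contrast = rms_contrast(rgb2gray(std))
    lo, hi = contrast_range
    passed = (lo <= contrast <= hi) and density > min_density
    return FilterReport("standard", density, passed, contrast=contrast), std
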