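"""Skew normalization of filtered tag crops.

A tag photographed off-axis is rotated in the image plane.  The tag's
dominant horizontal edge (its top or bottom rim) is recovered by Prewitt
edge detection on the colour-threshold mask followed by a Hough
transform; the incline angle theta = atan((y2-y1)/(x2-x1)) of the
longest near-horizontal line is then undone by rotating the crop by
-theta about its centre.

Sign convention: image y grows downward, so a baseline sloping down to
the right has positive theta and a counter-clockwise visual tilt is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import prewitt
from skimage.transform import probabilistic_hough_line, rotate

from .detection import NOISE_REMOVAL, HsvThresholds, hsv_mask, to_hsv_unit
from .errors import InputError, NormalizationError

__all__ = ["BaselineSegment", "detect_baseline", "skew_angle", "deskew"]

MAX_BASELINE_DEG = 45.0


@dataclass(frozen=True)
class BaselineSegment:
    """The detected base line of a tag crop, as endpoints plus slope."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    slope_m: float
    theta_deg: float

    def __post_init__(self) -> None:
        if self.p1[0] == self.p2[0]:
            raise ValueError("baseline cannot be vertical")
        if abs(self.theta_deg) > MAX_BASELINE_DEG:
            raise ValueError("baseline steeper than 45 degrees")


def skew_angle(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Incline angle in degrees of the segment p1 -> p2."""
    (x1, y1), (x2, y2) = p1, p2
    if x2 == x1:
        raise InputError("vertical segment has no incline angle")
    return math.degrees(math.atan((y2 - y1) / (x2 - x1)))


def detect_baseline(
    tag_crop: np.ndarray,
    thresholds: HsvThresholds = NOISE_REMOVAL,
) -> BaselineSegment:
    """Find the longest near-horizontal line of the crop's mask edges.

    The colour mask is edge-detected with the Prewitt operator and the
    edge map fed to a (probabilistic) Hough transform.  Among detected
    lines with |theta| <= 45 deg the longest wins; ties break toward
    smaller |theta|.  Raises :class:`NormalizationError` when no line is
    found.
    """
    mask = hsv_mask(to_hsv_unit(tag_crop), thresholds)
    edges = prewitt(mask.astype(float)) > 0.1
    min_len = max(10, mask.shape[1] // 4)
    lines = probabilistic_hough_line(
        edges, threshold=10, line_length=min_len, line_gap=3,
        rng=np.random.default_rng(0),
    )
    best = None
    best_key = None
    for (x1, y1), (x2, y2) in lines:
        if x1 == x2:
            continue
        theta = skew_angle((x1, y1), (x2, y2))
        if abs(theta) > MAX_BASELINE_DEG:
            continue
        length = math.hypot(x2 - x1, y2 - y1)
        key = (-length, abs(theta))
        if best_key is None or key < best_key:
            best_key = key
            m = (y2 - y1) / (x2 - x1)
            best = BaselineSegment((float(x1), float(y1)), (float(x2), float(y2)),
                                   m, theta)
    if best is None:
        raise NormalizationError("no baseline found in crop")
    return best


def _border_median(image: np.ndarray) -> np.ndarray:
    border = np.concatenate([
        image[0].reshape(-1, image.shape[-1]),
        image[-1].reshape(-1, image.shape[-1]),
        image[:, 0].reshape(-1, image.shape[-1]),
        image[:, -1].reshape(-1, image.shape[-1]),
    ])
    return np.median(border, axis=0)


def deskew(tag_crop: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate the crop by -theta_deg about its centre.

    The canvas is expanded so no content is clipped; uncovered pixels
    take the median border colour.  Bilinear interpolation.
    """
    if abs(theta_deg) > MAX_BASELINE_DEG:
        raise InputError("refusing to deskew by more than 45 degrees")
    if theta_deg == 0.0:
        return tag_crop.copy()
    img = np.asarray(tag_crop, dtype=np.float64) / 255.0
    # rotate(angle=theta) lowers the measured baseline angle by theta
    out = rotate(img, theta_deg, resize=True, order=1,
                 mode="constant", cval=-1.0)
    fill = _border_median(img)
    uncovered = out[..., 0] < 0
    out[uncovered] = fill
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)
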