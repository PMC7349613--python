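"""Head localization and stall assignment.

Head detection itself is pluggable: any callable mapping an RGB frame to
``(box, score)`` pairs satisfies the detector contract (a trained object
detector, the ground-truth stub used in tests, or the bundled dark-blob
detector).  Each detection is then assigned to one of five pre-allocated
stall regions by the containment of its box centre.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.measure import label, regionprops

from .errors import ConfigError
from .geometry import Box

__all__ = [
    "StallLayout",
    "HeadDetection",
    "detect_heads",
    "assign_stall",
    "GroundTruthDetector",
    "BlobHeadDetector",
]

Detector = Callable[[np.ndarray], Iterable[tuple[Box, float]]]


@dataclass(frozen=True)
class StallLayout:
    """Five disjoint stall regions, ordered left to right (positions 1-5)."""

    regions: tuple[Box, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigError("layout needs at least one region")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.x1 > b.x0:
                raise ConfigError("stall regions must be disjoint and ordered")

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "StallLayout":
        """Build from [x0, y0, x1, y1] rows (the YAML config format)."""
        return cls(tuple(Box(*map(int, r)) for r in rows))


@dataclass(frozen=True)
class HeadDetection:
    box: Box
    score: float
    position: Optional[int] = None  # 1-based stall position once assigned

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def detect_heads(frame: np.ndarray, detector: Detector) -> list[HeadDetection]:
    """Run the detector and return its output sorted by box left edge."""
    dets = [HeadDetection(box, float(score)) for box, score in detector(frame)]
    dets.sort(key=lambda d: d.box.x0)
    return dets


def assign_stall(det: HeadDetection, layout: StallLayout) -> Optional[int]:
    """Stall position whose region contains the box centre, else None."""
    cx, cy = det.box.center
    for pos, region in enumerate(layout.regions, start=1):
        if region.contains_point(cx, cy):
            return pos
    return None


def assign_all(dets: Iterable[HeadDetection], layout: StallLayout) -> list[HeadDetection]:
    return [replace(d, position=assign_stall(d, layout)) for d in dets]


class GroundTruthDetector:
    """Detector stub that echoes renderer ground truth (for tests)."""

    def __init__(self, truths) -> None:
        self._boxes = [t.head_box for t in truths]

    def __call__(self, frame: np.ndarray) -> list[tuple[Box, float]]:
        return [(b, 1.0) for b in self._boxes]


class BlobHeadDetector:
    """Find dark elliptical blobs (head proxies in rendered scenes).

    Thresholds the grayscale frame, labels connected dark components and
    returns boxes of those above ``min_area``, expanded by ``pad`` so the
    attached ear tag falls inside the head crop.
    """

    def __init__(self, gray_max: float = 0.33, min_area: int = 1500,
                 pad_side: int = 12, pad_top: int = 6, pad_bottom: int = 48) -> None:
        self.gray_max = gray_max
        self.min_area = min_area
        self.pad_side = pad_side
        self.pad_top = pad_top
        self.pad_bottom = pad_bottom

    def __call__(self, frame: np.ndarray) -> list[tuple[Box, float]]:
        gray = rgb2gray(frame)
        h, w = gray.shape
        out = []
        for region in regionprops(label(gray < self.gray_max)):
            if region.area < self.min_area:
                continue
            r0, c0, r1, c1 = region.bbox
            box = Box(max(0, c0 - self.pad_side), max(0, r0 - self.pad_top),
                      min(w, c1 + self.pad_side), min(h, r1 + self.pad_bottom))
            out.append((box, min(1.0, region.area / (4.0 * self.min_area))))
        return out
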