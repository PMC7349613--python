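"""Axis-aligned boxes in image coordinates.

Convention used throughout the package: ``x`` indexes columns, ``y``
indexes rows, boxes are half-open (``x0 <= x < x1``), 0-based.
"""

from __future__ import annotations

from typing import NamedTuple


class Box(NamedTuple):
    """Half-open axis-aligned rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return max(0, self.width) * max(0, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def intersect(self, other: "Box") -> "Box":
        return Box(
            max(self.x0, other.x0),
            max(self.y0, other.y0),
            min(self.x1, other.x1),
            min(self.y1, other.y1),
        )

    def iou(self, other: "Box") -> float:
        inter = self.intersect(other).area
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def shift(self, dx: int, dy: int) -> "Box":
        return Box(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)
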