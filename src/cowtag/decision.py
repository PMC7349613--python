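"""Windowed temporal decision over per-frame head detections.

Per-frame detector output is noisy: a head may be missed for a few
frames, or briefly appear in a neighbouring stall's region of interest
(ROI).  Decisions are therefore taken over tumbling windows (default 30
frames, i.e. ~30 s at one processed frame per second): an ROI is deemed
occupied when a head was detected there in strictly more than half of
the window's frames.  The same mechanism smooths confirmed-tag presence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DecisionTable",
    "PresenceResult",
    "decide_presence",
    "stream_windows",
]

DEFAULT_WINDOW = 30


@dataclass(frozen=True)
class DecisionTable:
    """window_size x n_roi boolean flags; flags[f, r] = head seen in ROI
    r at frame f of the window."""

    flags: np.ndarray
    window_size: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        object.__setattr__(self, "flags", flags)
        if flags.ndim != 2:
            raise ValueError("flags must be 2-D (frames x ROIs)")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    @property
    def n_roi(self) -> int:
        return self.flags.shape[1]


@dataclass(frozen=True)
class PresenceResult:
    """Per-ROI occupancy decision for one window.

    ``percentage`` is truncated to an integer (floor), matching the
    convention that 5/30 reports as 16%, not 17%.
    """

    occurrence_count: tuple[int, ...]
    percentage: tuple[int, ...]
    present: tuple[bool, ...]


def decide_presence(table: DecisionTable) -> PresenceResult:
    """Occupancy per ROI: present iff count > 50% of the window (strict)."""
    if table.flags.shape[0] != table.window_size:
        raise ValueError(
            f"partial window: {table.flags.shape[0]} rows, "
            f"expected {table.window_size}"
        )
    counts = table.flags.sum(axis=0)
    pct = (100 * counts) // table.window_size  # floor
    present = counts * 2 > table.window_size
    return PresenceResult(
        occurrence_count=tuple(int(c) for c in counts),
        percentage=tuple(int(p) for p in pct),
        present=tuple(bool(p) for p in present),
    )


def stream_windows(
    per_frame_flags: Iterable[Sequence[bool]],
    window_size: int = DEFAULT_WINDOW,
) -> list[DecisionTable]:
    """Chop a stream of per-frame ROI flags into tumbling windows.

    Windows do not overlap; a trailing partial window is discarded.
    """
    rows = [np.asarray(r, dtype=bool) for r in per_frame_flags]
    n_full = len(rows) // window_size
    out = []
    for w in range(n_full):
        block = np.stack(rows[w * window_size : (w + 1) * window_size])
        out.append(DecisionTable(block, window_size))
    return out


# Worked example: occurrence counts of one 30-frame window over five ROIs
# (three occupied stalls, two spurious/transient ones).
WORKED_EXAMPLE_COUNTS: tuple[int, ...] = (27, 5, 30, 3, 27)


def worked_example_table(seed: int = 0) -> DecisionTable:
    """A 30x5 decision table whose column sums equal the bundled
    worked-example occurrence counts (row placement randomized)."""
    rng = np.random.default_rng(seed)
    flags = np.zeros((DEFAULT_WINDOW, len(WORKED_EXAMPLE_COUNTS)), dtype=bool)
    for roi, count in enumerate(WORKED_EXAMPLE_COUNTS):
        rows = rng.choice(DEFAULT_WINDOW, size=count, replace=False)
        flags[rows, roi] = True
    return DecisionTable(flags, DEFAULT_WINDOW)
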