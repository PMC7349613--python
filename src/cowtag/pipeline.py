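"""End-to-end processing: frames in, confirmed cow locations out.

Per frame: detect heads, assign each to a stall, extract and filter tag
candidates from the head crop, deskew, segment digits, classify, and
confirm the recognized string against the roster.  Per tumbling window
(default 30 frames): decide per-stall occupancy from head detections and
collapse the window's confirmed tags to one tag per stall, emitting a
:class:`LocationRecord` for every occupied stall with a confirmed tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import confirmation as conf
from .classifier import DigitModel, recognize_tag
from .config import PipelineConfig
from .decision import DecisionTable, decide_presence
from .detection import (
    extract_tag_candidates,
    initial_noise_filter,
    standard_image_filter,
)
from .errors import InputError, NormalizationError, SegmentationError
from .localization import Detector, assign_all, detect_heads
from .normalization import deskew, detect_baseline
from .segmentation import segment_digits

logger = logging.getLogger(__name__)

__all__ = ["LocationRecord", "PipelineResult", "run_pipeline", "search"]


@dataclass(frozen=True)
class LocationRecord:
    """One confirmed (tag, stall) pairing for one decision window."""

    tag_id: str
    camera: int
    position: int
    window_index: int


@dataclass
class PipelineResult:
    records: list[LocationRecord]
    window_reports: list[dict]
    confirmation_log: list[dict]

    def to_frames(self):
        """Confirmation log as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            self.confirmation_log,
            columns=["frame", "camera", "position", "raw", "rule", "tag"],
        )


def _read_tag(head_crop: np.ndarray, cfg: PipelineConfig,
              classifier: DigitModel, frame_id: int, position: int) -> Optional[str]:
    """Head crop -> raw recognized string, or None when nothing survives."""
    candidates = extract_tag_candidates(
        head_crop, frame_id, position,
        thresholds=cfg.tag_thresholds,
        min_area=cfg.min_component_area,
        pad=cfg.candidate_pad,
    )
    for cand in candidates:
        report = initial_noise_filter(cand, cfg.noise_thresholds,
                                      cfg.initial_density_range)
        if not report.passed:
            continue
        report, std = standard_image_filter(
            cand, cfg.noise_thresholds, cfg.contrast_range,
            cfg.min_standard_density, cfg.standard_size,
        )
        if not report.passed:
            continue
        try:
            baseline = detect_baseline(std, cfg.noise_thresholds)
            crop = deskew(std, baseline.theta_deg)
        except NormalizationError:
            continue
        # re-tighten to the tag component: border removal assumes the
        # crop's margins are tag field, not head/background
        inner = extract_tag_candidates(
            crop, frame_id, position,
            thresholds=cfg.tag_thresholds,
            min_area=cfg.min_component_area,
            pad=0,
        )
        if inner:
            largest = max(inner, key=lambda c: c.source_box.area)
            crop = largest.image
        try:
            segments = segment_digits(
                crop,
                gray_threshold=cfg.gray_threshold,
                min_width_frac=cfg.min_digit_width_frac,
                start_fraction=cfg.start_fraction,
                start_fraction_axis=cfg.start_fraction_axis,
            )
        except SegmentationError:
            continue
        crops = [c for seg in segments for c in seg.crops]
        raw = recognize_tag(classifier, crops)
        if raw:
            return raw
    return None


def run_pipeline(
    frames: Iterable[np.ndarray],
    config: PipelineConfig,
    detector: Detector,
    classifier: DigitModel,
    roster: Optional[conf.Roster] = None,
) -> PipelineResult:
    """Process a frame stream into location records and window reports.

    ``frames`` is an iterable of RGB arrays (already subsampled to the
    processing rate).  Deterministic given fixed detector, classifier
    weights and config.
    """
    if roster is None:
        if config.roster_path is None:
            raise InputError("no roster: pass one or set roster_path")
        roster = conf.Roster.from_file(config.roster_path)
    lists = conf.build_checklists(roster)
    layout = config.layout
    n_roi = len(layout.regions)
    history = conf.TagHistory()

    records: list[LocationRecord] = []
    reports: list[dict] = []
    log: list[dict] = []
    head_flags: list[list[bool]] = []
    window_tags: dict[int, list[str]] = {p: [] for p in range(1, n_roi + 1)}
    window_index = 0
    n_frames = 0

    def close_window() -> None:
        nonlocal window_index
        table = DecisionTable(np.array(head_flags[-config.window_size:]),
                              config.window_size)
        presence = decide_presence(table)
        report = {"camera": config.camera, "window_index": window_index, "roi": {}}
        for pos in range(1, n_roi + 1):
            tag = conf.update_final_list(window_tags[pos])
            present = presence.present[pos - 1]
            if tag is not None:
                history.set_final(config.camera, pos, tag)
            if present and tag is not None:
                records.append(LocationRecord(tag, config.camera, pos, window_index))
            report["roi"][pos] = {
                "count": presence.occurrence_count[pos - 1],
                "percentage": presence.percentage[pos - 1],
                "present": present,
                "tag": tag if present else None,
            }
            window_tags[pos] = []
        reports.append(report)
        window_index += 1

    for frame_id, frame in enumerate(frames):
        n_frames += 1
        dets = assign_all(detect_heads(frame, detector), layout)
        flags = [False] * n_roi
        for det in dets:
            if det.position is None:
                continue
            flags[det.position - 1] = True
            b = det.box
            head_crop = frame[max(0, b.y0) : b.y1, max(0, b.x0) : b.x1]
            raw = _read_tag(head_crop, config, classifier, frame_id, det.position)
            result = conf.confirm_tag(
                raw, lists, history.get(config.camera, det.position)
            )
            log.append({
                "frame": frame_id, "camera": config.camera,
                "position": det.position, "raw": raw or "",
                "rule": result.rule, "tag": result.tag or "",
            })
            if result.status == "saved":
                history.record(config.camera, det.position, result.tag)
                window_tags[det.position].append(result.tag)
        head_flags.append(flags)
        if len(head_flags) % config.window_size == 0:
            close_window()
    logger.info("processed %d frames -> %d windows, %d records",
                n_frames, len(reports), len(records))
    return PipelineResult(records, reports, log)


def search(
    tag_id: str, records: Sequence[LocationRecord]
) -> Optional[tuple[int, int]]:
    """Most recent (camera, position) for a 4-digit tag, else None."""
    if not (isinstance(tag_id, str) and len(tag_id) == 4 and tag_id.isdigit()):
        raise InputError(f"query must be a 4-digit string, got {tag_id!r}")
    for rec in reversed(list(records)):
        if rec.tag_id == tag_id:
            return rec.camera, rec.position
    return None
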