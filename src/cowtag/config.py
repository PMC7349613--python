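"""Pipeline configuration.

Every numeric constant of the processing chain lives here with its
default; presets can be overridden from a YAML file or CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Literal, Optional

import yaml

from .detection import NOISE_REMOVAL, TAG_DETECTION, HsvThresholds
from .errors import ConfigError
from .localization import StallLayout
from .synthetic import default_layout

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # HSV threshold presets
    tag_thresholds: HsvThresholds = TAG_DETECTION
    noise_thresholds: HsvThresholds = NOISE_REMOVAL
    # candidate extraction
    min_component_area: int = 100
    candidate_pad: int = 4
    # quality filters
    initial_density_range: tuple[int, int] = (400, 2700)
    contrast_range: tuple[float, float] = (0.17, 0.65)
    min_standard_density: int = 15500  # strict >
    standard_size: int = 200
    # segmentation constants
    barcode_min_row_frac: float = 0.25
    digit_height_ratio: float = 1.7
    barcode_object_width_frac: float = 0.5
    start_fraction: float = 0.45
    start_fraction_axis: Literal["height", "width"] = "height"
    min_digit_width_frac: float = 1.0 / 6.0
    gray_threshold: int = 150
    object_height_frac: float = 2.0 / 3.0
    # confirmation
    three_digit_mode: Literal["delete_one", "contiguous"] = "delete_one"
    # temporal decision
    window_size: int = 30
    frame_stride: int = 25  # process one frame per second of 25 fps video
    # identity / IO
    camera: int = 1
    roster_path: Optional[str] = None
    seed: int = 0
    stall_rows: tuple[tuple[int, int, int, int], ...] = field(
        default_factory=lambda: tuple(tuple(b) for b in default_layout())
    )

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ConfigError("window_size must be >= 1")
        if self.frame_stride < 1:
            raise ConfigError("frame_stride must be >= 1")
        lo, hi = self.initial_density_range
        if lo > hi or lo < 0:
            raise ConfigError("invalid initial_density_range")
        if self.start_fraction_axis not in ("height", "width"):
            raise ConfigError("start_fraction_axis must be 'height' or 'width'")

    @property
    def layout(self) -> StallLayout:
        return StallLayout.from_rows(self.stall_rows)


def _to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["tag_thresholds"] = asdict(cfg.tag_thresholds)
    d["noise_thresholds"] = asdict(cfg.noise_thresholds)
    d["stall_rows"] = [list(r) for r in cfg.stall_rows]
    return d


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown fields raise :class:`ConfigError`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    for key in ("tag_thresholds", "noise_thresholds"):
        if key in raw:
            try:
                raw[key] = HsvThresholds(**raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad {key}: {exc}") from exc
    if "stall_rows" in raw:
        raw["stall_rows"] = tuple(tuple(int(v) for v in r) for r in raw["stall_rows"])
    for key in ("initial_density_range", "contrast_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
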