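"""Exception hierarchy."""


class CowtagError(Exception):
    """Base class for all package errors."""


class InputError(CowtagError, ValueError):
    """Malformed caller input (bad shapes, bad strings, bad parameters)."""


class ConfigError(CowtagError, ValueError):
    """Invalid pipeline configuration."""


class NormalizationError(CowtagError):
    """No usable baseline found; the caller skips the crop."""


class SegmentationError(CowtagError):
    """Digit segmentation failed for a crop (e.g. everything trimmed)."""


class SegmentRejected(SegmentationError):
    """A column span contained no qualifying digit object."""
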