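"""Exception hierarchy for the skinoct pipeline."""


class SkinOctError(Exception):
    """Base class for all skinoct-specific errors."""


class ValidationError(SkinOctError):
    """Invalid parameter, vocabulary, or data-contract violation."""


class FormatError(SkinOctError):
    """On-disk data malformed or inconsistent with its sidecar metadata."""


class CalibrationError(SkinOctError):
    """Reference-intensity calibration could not be established."""


class SegmentationError(SkinOctError):
    """Layer segmentation failed for an entire volume."""
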