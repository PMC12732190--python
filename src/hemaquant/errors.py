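"""Exception hierarchy.

All package errors derive from :class:`HemaquantError` so callers can catch
one base class; the CLI maps these to exit code 3 (input error) except QC
failures, which use exit code 2.
"""


class HemaquantError(Exception):
    """Base class for all hemaquant errors."""


class CalibrationError(HemaquantError):
    """Invalid pixel-scale calibration input (non-positive length)."""


class FormatError(HemaquantError):
    """Unsupported image format (e.g. channel count)."""


class MeasurementError(HemaquantError):
    """ROI falls outside the image, or measurement inputs are inconsistent."""


class InsufficientControlsError(HemaquantError):
    """Fewer than two negative-control wells; the mean+3SD rule is undefined."""


class FitError(HemaquantError):
    """Degenerate standard-curve design (too few or identical amounts)."""


class QuantitationError(HemaquantError):
    """Back-calculation impossible (e.g. non-positive standard-curve slope)."""


class ConfigError(HemaquantError):
    """Run configuration missing required blocks or inconsistent."""
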