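"""Exception hierarchy for the preycap pipeline.

All errors derive from :class:`PreycapError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class PreycapError(Exception):
    """Base class for all preycap errors."""


class InvalidParameterError(PreycapError, ValueError):
    """A generator or analysis parameter is out of its valid range."""


class OutOfBoundsError(PreycapError, ValueError):
    """Geometry falls outside the image frame."""


class CalibrationError(PreycapError, ValueError):
    """Tail-tracker calibration failed (e.g. base point on background)."""


class VideoQualityError(PreycapError, ValueError):
    """Too many frames failed tracking for the trace to be trusted."""


class InvalidLayoutError(PreycapError, ValueError):
    """ROI masks overlap or fall outside the frame."""


class InvalidWindowError(PreycapError, ValueError):
    """A temporal window is incompatible with the movie length."""


class InvalidBandError(PreycapError, ValueError):
    """A frequency band lies outside the signal's Nyquist range."""


class InsufficientDataError(PreycapError, ValueError):
    """Too few samples for the requested statistical test."""


class SchemaError(PreycapError, ValueError):
    """A serialized artifact does not match the expected schema."""


class StratificationError(PreycapError, ValueError):
    """A class has too few members for the requested fold count."""


class BoutTooShortError(PreycapError, ValueError):
    """Bout has too few frames for feature extraction."""
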