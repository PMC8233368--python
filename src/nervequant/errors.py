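"""Exception hierarchy for nervequant.

All validation/contract failures derive from :class:`NervequantError` so batch
drivers can catch one base class; plain bugs still surface as standard Python
exceptions.
"""


class NervequantError(Exception):
    """Base class for all nervequant-specific errors."""


class FormatError(NervequantError, ValueError):
    """An input file has an unsupported format property (bit depth, channels,
    ROI subtype). The message names the offending property."""


class ValidationError(NervequantError, ValueError):
    """A domain object or argument violates its contract."""


class EmptyRegionError(ValidationError):
    """An operation that needs at least one ROI pixel received an empty mask."""


class DegenerateHistogramError(ValidationError):
    """A histogram with fewer than two occupied bins cannot be thresholded.

    Callers decide the fallback: B-mode FR reports 0 with a degenerate flag,
    Doppler signal selection returns an empty mask (absent flow is a valid
    observation).
    """


class CalibrationError(ValidationError):
    """A physical-units result was requested without pixel-area calibration."""


class ParameterError(ValidationError):
    """A numeric parameter is outside its admissible range."""


class GenerationError(NervequantError, RuntimeError):
    """The synthetic generator could not satisfy the requested ground truth."""


class UndefinedCorrelationError(ValidationError):
    """Correlation requested on a metric with zero variance."""
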