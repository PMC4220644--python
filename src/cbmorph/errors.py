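"""Exception hierarchy for cbmorph.

All errors derive from ValueError so callers that do not care about the
fine-grained category can catch a single type.
"""


class CBMorphError(ValueError):
    """Base class for all cbmorph errors."""


class InvalidArgumentError(CBMorphError):
    """A parameter violates a documented precondition."""


class InvalidInputError(CBMorphError):
    """An input image/array has the wrong shape, dtype, or normalization."""


class DegenerateImageError(CBMorphError):
    """The image admits no meaningful result (e.g. constant image for Otsu)."""


class InsufficientForegroundError(CBMorphError):
    """Too few foreground pixels for the statistic to be defined."""


class EmptyPatternError(CBMorphError):
    """Operation requires a non-empty binary pattern."""


class RegressionDegenerateError(CBMorphError):
    """Fewer than two usable scales for the log-log regression."""


class CalibrationError(CBMorphError):
    """Bisection calibration could not reach the requested target."""
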