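"""Exception hierarchy for screening-pipeline failures.

Every error raised on bad scientific input derives from :class:`SynscreenError`
so callers (and the CLI) can distinguish pipeline rejections from bugs.
"""


class SynscreenError(ValueError):
    """Base class for all input / analysis errors raised by this package."""


class InputFormatError(SynscreenError):
    """Malformed plate or growth table (missing column, bad value, duplicate well)."""


class InsufficientControlsError(SynscreenError):
    """Fewer than two control wells on one side of the Z'-factor computation."""


class UndefinedSeparationError(SynscreenError):
    """Positive and negative control means coincide; Z' is undefined."""


class DegenerateControlError(SynscreenError):
    """Vehicle-control signal does not exceed blank; normalization undefined."""


class IncompleteBlockError(SynscreenError):
    """A checkerboard block is missing wells; no imputation is performed."""


class InsufficientDataError(SynscreenError):
    """Too few usable points for a dose-response fit."""


class FitFailureError(SynscreenError):
    """Nonlinear fit did not converge."""


class OutOfRangeError(SynscreenError):
    """A fraction-affected or score argument is outside its valid range."""


class AlignmentError(SynscreenError):
    """Treatment arms share no common measurement days."""


class UndefinedTGIError(SynscreenError):
    """Control arm shows zero net volume change; TGI is undefined."""
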