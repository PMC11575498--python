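"""Exception hierarchy for the coordination-analysis pipeline.

Every stage raises a subclass of :class:`DyadcoordError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class DyadcoordError(Exception):
    """Base class for all package errors."""


class FormatError(DyadcoordError):
    """A file does not conform to the expected dialect (e.g. missing the
    three-row pose-estimation CSV header)."""


class ParseError(DyadcoordError):
    """A file matched the dialect but a row/field could not be parsed."""


class ConfigError(DyadcoordError):
    """Invalid configuration, e.g. a marker-name mapping that does not cover
    the four required hand markers."""


class ParameterError(DyadcoordError):
    """An operation received an invalid parameter value."""


class InputError(DyadcoordError):
    """Input data violate an operation's precondition (too short, mismatched
    lengths, wrong pairing set...)."""


class UnusableMarkerError(DyadcoordError):
    """Every sample of a marker fell below the likelihood cutoff."""


class LengthError(DyadcoordError):
    """A series is shorter than the expected session length."""


class UnclassifiableMomentError(DyadcoordError):
    """A moment contains no defined coordination-metric samples."""


class UndefinedThresholdError(DyadcoordError):
    """The data-sliding surrogate distribution is empty (all windows
    degenerate), so no significance threshold exists."""


class EpisodeSpecError(DyadcoordError):
    """Invalid synthetic-session episode script (overlap, bad ordering...)."""
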