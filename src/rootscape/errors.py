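"""Exception hierarchy.

Every rootscape error derives from :class:`RootscapeError`, so callers can
catch one type at a pipeline boundary. Subclasses map onto the failure
classes the library distinguishes: bad parameters, unreadable inputs,
schema mismatches, and measurements requested on degenerate inputs.
"""


class RootscapeError(Exception):
    """Base class for all rootscape errors."""


class ParameterError(RootscapeError, ValueError):
    """A function argument is outside its documented domain."""


class FormatError(RootscapeError, ValueError):
    """A file exists but is not in a supported format/bit depth."""


class ParseError(RootscapeError, ValueError):
    """A filename does not match the configured metadata pattern."""


class ValidationError(RootscapeError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class SchemaError(RootscapeError, ValueError):
    """A table on disk does not match the trait registry."""


class TrainingError(RootscapeError, ValueError):
    """The segmentation model cannot be trained from the given library."""


class MeasurementError(RootscapeError, ValueError):
    """A measurement was requested on a degenerate input (e.g. empty mask)."""


class StatisticsError(RootscapeError, ValueError):
    """Too few observations for the requested statistic."""
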