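"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`ScreenError` so callers can catch
pipeline failures without masking programming errors.
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ScreenError):
    """A parameter or window violates a stage's preconditions."""


class SizingError(ConfigurationError):
    """A library design does not fit the requested number of plates."""


class TraceFormatError(ScreenError):
    """A plate-trace file violates the documented dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ParseError(ScreenError):
    """A tabular input file (hit table, annotations, layout) is malformed."""


class DegeneratePlateError(ScreenError):
    """Plate standard deviation is zero; no Z-scores can be emitted."""


class InvalidControlError(ScreenError):
    """Control-well mean is non-positive; percent inhibition is undefined."""


class QCNotEvaluableError(ScreenError):
    """A plate is missing the well groups needed for the control gate."""


class InsufficientDataError(ScreenError):
    """Too few paired observations for the requested statistic."""


class MappingError(ScreenError):
    """An amplicon has no gene assignment."""


class ConsistencyError(ScreenError):
    """Derived counts disagree (e.g. more hits after filtering than before)."""


class IncompleteRunError(ScreenError):
    """A run directory is missing a stage output needed for reporting."""
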