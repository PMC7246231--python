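"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ``ValidationError`` subclasses map to exit
code 2 (bad parameters / config), ``DataError`` subclasses to exit code 3
(unusable input data).
"""


class RRBandError(Exception):
    """Base class for all package errors."""


class ValidationError(RRBandError):
    """Invalid parameter, configuration, or call contract violation."""


class InvalidParameterError(ValidationError):
    pass


class InvalidScenarioError(ValidationError):
    pass


class DataError(RRBandError):
    """Input data is present but unusable."""


class ParseError(DataError):
    """A signal or counts file could not be parsed; carries row context."""

    def __init__(self, message: str, path=None, row: int | None = None):
        self.path = path
        self.row = row
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f", row {row}]" if row is not None else "]"
        super().__init__(message + loc)


class NoBreathsError(DataError):
    """Fewer than two breath onsets were found in a 60-s window."""


class UncorrectableWindowError(DataError):
    """Every sample in the window is motion-flagged; nothing to interpolate from."""


class InsufficientDataError(DataError):
    """Too few paired deviations to compute agreement statistics."""


class EmptyResultError(DataError):
    """An operation produced no usable records (e.g. no overlapping minutes)."""
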