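"""Exception hierarchy for activcoach.

Every error raised by the library derives from :class:`ActivCoachError` so
callers (and the CLI) can distinguish library failures from programming
errors.
"""


class ActivCoachError(Exception):
    """Base class for all activcoach errors."""


class DataFormatError(ActivCoachError, ValueError):
    """A file does not conform to the expected column layout."""


class RowParseError(DataFormatError):
    """One or more data rows could not be parsed; carries line numbers."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = list(lines or [])


class DomainError(ActivCoachError, ValueError):
    """An input value lies outside its scientific domain (e.g. negative steps)."""


class ArityError(ActivCoachError, ValueError):
    """A sequence has the wrong length (weeks are 7 days, etc.)."""


class InsufficientDataError(ActivCoachError, ValueError):
    """Not enough observations to compute the requested quantity."""


class ConfigError(ActivCoachError, ValueError):
    """A configuration value is missing or invalid; names the offending key."""


class RenderError(ActivCoachError, KeyError):
    """A message template placeholder has no value; names the placeholder."""


class SchemaError(ActivCoachError, ValueError):
    """A knowledge-base instance references an undeclared variable or property."""
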