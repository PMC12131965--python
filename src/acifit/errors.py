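"""Exception hierarchy for acifit."""


class AcifitError(Exception):
    """Base class for all acifit errors."""


class EmptyInputError(AcifitError):
    """A file or table contained no data rows."""


class MissingColumnError(AcifitError):
    """A required column is absent from an input table."""

    def __init__(self, column: str, path: str = ""):
        self.column = column
        loc = f" in {path}" if path else ""
        super().__init__(f"required column {column!r} is missing{loc}")


class ParseError(AcifitError):
    """A cell could not be parsed; carries row/column location."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        super().__init__(message)


class ScheduleError(AcifitError):
    """A set-point schedule is inconsistent with a curve or itself."""


class ConfigurationError(AcifitError):
    """An unknown form, preset, or option was requested."""


class DomainError(AcifitError):
    """A model was evaluated outside its physical domain."""


class InfeasibleError(AcifitError):
    """A model equation has no real solution for the given parameters."""


class SingularityError(AcifitError):
    """An expression was evaluated at (or too close to) a pole."""
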