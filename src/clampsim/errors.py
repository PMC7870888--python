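"""Exception hierarchy for clampsim."""


class ClampsimError(Exception):
    """Base class for all clampsim errors."""


class ConfigurationError(ClampsimError):
    """Unknown model label, bad parameter bundle, or invalid configuration value."""


class InvalidInputError(ClampsimError, ValueError):
    """Physically meaningless input (non-positive concentration, fraction outside (0,1), ...)."""


class InvalidStateError(ClampsimError, ValueError):
    """Gate value or time constant outside its admissible range."""


class IntegrationError(ClampsimError):
    """The solver failed to advance; carries the last valid time reached."""

    def __init__(self, message: str, last_time_ms: float | None = None):
        super().__init__(message)
        self.last_time_ms = last_time_ms


class FitError(ClampsimError):
    """Nonlinear fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(ClampsimError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ExtrapolationError(ClampsimError):
    """A query fell outside the tabulated range of an interpolation accessor."""
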