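"""Package-wide exception types."""


class DomainError(ValueError):
    """An argument is outside the mathematically/biologically valid domain."""


class ParseError(ValueError):
    """A cohort file violates the expected schema or invariants."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FitError(RuntimeError):
    """Model fitting could not produce a result."""
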