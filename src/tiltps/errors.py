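"""Exception hierarchy shared across the package."""


class TiltPsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TiltPsError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(TiltPsError, ValueError):
    """Input data is degenerate or inconsistent (e.g. all-equal design points)."""


class FitFailureError(TiltPsError, RuntimeError):
    """An optimizer or model fit could not produce a usable result.

    Carries a ``diagnostics`` dict with whatever intermediate state the
    failing stage could collect.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptyResultError(TiltPsError, RuntimeError):
    """An operation legitimately produced nothing (e.g. all tiles filtered out)."""


class ContractViolationError(TiltPsError, RuntimeError):
    """An internal invariant that callers should have guaranteed was broken."""


class FormatError(TiltPsError, IOError):
    """A file could not be parsed; the message names the offending field/line."""
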