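"""Exception hierarchy shared across the package."""


class PsicascadeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PsicascadeError, ValueError):
    """Raised for physically meaningless inputs (negative concentrations, ...)."""


class IntegrationError(PsicascadeError, RuntimeError):
    """Raised when the ODE solver fails; carries the solver diagnostics."""


class DataError(PsicascadeError, ValueError):
    """Raised for malformed or degenerate datasets."""
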