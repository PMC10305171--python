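"""Exception hierarchy for the tracegas package."""


class TracegasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TracegasError):
    """A constants/config lookup failed (unknown gas, matrix, or preset)."""


class ValidationError(TracegasError, ValueError):
    """An input value violates a precondition (negative concentration, ...)."""


class DomainError(TracegasError, ValueError):
    """A physically meaningful input lies outside the supported domain."""


class FitError(TracegasError):
    """A kinetic fit or model selection could not be completed."""
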