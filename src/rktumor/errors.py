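"""Package exception hierarchy."""


class RKTumorError(Exception):
    """Base class for package errors."""


class InvalidInputError(RKTumorError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(RKTumorError, ValueError):
    """A configuration is internally inconsistent (e.g. event probability > 1)."""


class IntegrationError(RKTumorError, ArithmeticError):
    """Numerical integration produced non-finite values."""
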