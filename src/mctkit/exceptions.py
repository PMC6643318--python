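"""Exception hierarchy for mctkit."""


class MCTError(Exception):
    """Base class for all mctkit errors."""


class SchemaError(MCTError, ValueError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(MCTError, ValueError):
    """Input values violate a contract (duplicates, negative volumes, ...)."""


class InsufficientDataError(MCTError, ValueError):
    """Too few observations to carry out the requested computation."""


class ExtrapolationError(MCTError, ValueError):
    """A volume was requested outside a curve's measured day range."""


class UndefinedEndpointError(MCTError, ValueError):
    """An endpoint is mathematically undefined on the given input
    (zero baseline volume, zero vehicle growth, ...)."""


class ConvergenceError(MCTError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostic information."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
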