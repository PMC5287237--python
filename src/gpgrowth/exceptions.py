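"""Exception hierarchy for gpgrowth."""


class GPGrowthError(Exception):
    """Base class for all gpgrowth errors."""


class SchemaError(GPGrowthError, ValueError):
    """A required column is missing or mis-mapped in an input table."""


class ParseError(GPGrowthError, ValueError):
    """A cell could not be parsed as the expected numeric type."""


class ValidationError(GPGrowthError, ValueError):
    """A table violates a structural invariant (e.g. duplicate time points)."""


class DomainError(GPGrowthError, ValueError):
    """Input values are outside the mathematical domain of an operation."""


class ParameterError(GPGrowthError, ValueError):
    """A kernel or model parameter is invalid (non-positive scale, wrong shape)."""


class NumericalError(GPGrowthError, RuntimeError):
    """A linear-algebra step failed beyond recoverable jitter."""


class FitError(GPGrowthError, RuntimeError):
    """Hyperparameter optimization failed on all restarts."""
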