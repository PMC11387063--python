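"""Exception hierarchy shared across modules."""


class OwlPathError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OwlPathError):
    """An invalid configuration value; the message names the offending field."""


class DataError(OwlPathError):
    """Input data violate a model contract (e.g. negative counts)."""


class ChainViolationError(DataError):
    """The reproduction chain constraint 0 <= F <= N <= E is violated."""


class IllegalHistoryError(DataError):
    """An encounter history violates the coding rules."""


class DegenerateDesignError(OwlPathError):
    """A regression design matrix is rank-deficient."""


class ConstantCovariateError(OwlPathError):
    """A covariate has zero spread and cannot be standardized."""


class SchemaError(OwlPathError):
    """A tabular input does not match the expected schema."""


class ImputationError(OwlPathError):
    """No observed values are available to anchor an imputation group."""


class InitializationError(OwlPathError):
    """The posterior is not finite at the MCMC initial values."""
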