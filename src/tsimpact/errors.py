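"""Exception types used across the package."""


class TsimpactError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsimpactError, ValueError):
    """Invalid configuration (generator, folds, pruning settings...)."""


class ValidationError(TsimpactError, ValueError):
    """Invalid data passed to a fitting or evaluation routine."""


class PartitionError(TsimpactError, ValueError):
    """A fuzzy partition could not be derived for a domain."""


class NotFittedError(TsimpactError, RuntimeError):
    """Model used before its consequents were estimated."""
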