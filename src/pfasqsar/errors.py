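"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, DivergenceError -> 4.
"""


class PfasQsarError(Exception):
    """Base class for all package errors."""


class ConfigError(PfasQsarError):
    """Invalid, unknown, or missing configuration."""


class DataError(PfasQsarError):
    """Invalid input data."""


class SchemaError(DataError):
    """Input table is missing a mandatory column."""


class ValidationError(DataError):
    """A record violates an invariant (e.g. duplicate id)."""


class FeaturizationError(DataError):
    """A molecule could not be featurized."""


class InsufficientLabelsError(DataError):
    """Not enough labeled records to build pair constraints."""


class DimensionError(DataError):
    """Array dimensions are inconsistent with the operation."""


class ParameterError(DataError):
    """A numeric parameter is outside its valid range."""


class PatternError(DataError):
    """A SMARTS pattern failed to parse."""


class DivergenceError(PfasQsarError):
    """Optimization produced a non-finite loss."""
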