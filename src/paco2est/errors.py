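"""Exception hierarchy for the PaCO2 estimation pipeline."""


class Paco2EstError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(Paco2EstError):
    """A configuration value violates its documented constraints."""


class DomainError(Paco2EstError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateScaleError(Paco2EstError):
    """The robust residual scale collapsed to zero (MAD of residuals is 0)."""


class SingularDesignError(Paco2EstError):
    """The regression design matrix is rank deficient."""


class DesignMatrixError(Paco2EstError):
    """A transformed cell of the design matrix is non-finite."""


class InsufficientDataError(Paco2EstError):
    """Too few observations for the requested statistic."""


class SchemaError(Paco2EstError):
    """A serialized artifact does not match the expected schema or version."""


class ParseError(Paco2EstError):
    """A file could not be parsed into the documented structures."""


class UnitError(Paco2EstError):
    """A declared unit does not match the canonical unit of a channel."""


class ConsistencyError(Paco2EstError):
    """Inputs that must refer to identical underlying data do not."""
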