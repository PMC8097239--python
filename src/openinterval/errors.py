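"""Exception hierarchy for the openinterval package."""


class OpenIntervalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OpenIntervalError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(OpenIntervalError):
    """A CSV file does not match the documented survey schema."""


class RowValidationError(OpenIntervalError):
    """A microdata row violates a record invariant (fatal mode)."""


class FixtureIntegrityError(OpenIntervalError):
    """A packaged data fixture fails its integrity checks."""


class DomainError(OpenIntervalError):
    """An argument lies outside the mathematical domain of an operation."""


class EmptyInputError(OpenIntervalError):
    """No eligible records remain after filtering."""


class InsufficientDataError(OpenIntervalError):
    """Too few positive bins (or rows) to fit the requested model."""


class UndefinedCorrelationError(OpenIntervalError):
    """Correlation requested on a constant or too-short series."""


class StationarityError(OpenIntervalError):
    """An observed distribution violates the stationarity assumption."""
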