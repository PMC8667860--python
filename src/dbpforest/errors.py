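"""Exception hierarchy shared across the package."""


class DBPForestError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DBPForestError):
    """A file did not conform to the expected on-disk layout."""


class ValidationError(DBPForestError):
    """An in-memory object or argument violates a documented precondition."""


class EmptyInputError(DBPForestError):
    """An input file or directory contained no usable records."""


class DegenerateInputError(DBPForestError):
    """Input is structurally valid but too small for the operation (e.g. L < 2)."""


class SchemaError(DBPForestError):
    """Feature names or columns do not match between two tables/models."""
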