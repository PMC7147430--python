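"""Exception hierarchy shared across the package."""


class SeedHTTError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SeedHTTError, ValueError):
    """An input table is missing a required column or has an invalid layout."""


class ValidationError(SeedHTTError, ValueError):
    """An input value violates a data invariant (e.g. decreasing cumulative counts)."""


class ModelMisfitError(SeedHTTError, RuntimeError):
    """The fitted model contradicts its own assumptions (e.g. non-positive probit slope)."""


class NonIdentifiableError(SeedHTTError, RuntimeError):
    """The data carry no information on a parameter the model needs."""
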