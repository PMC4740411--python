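"""Exception types shared across the package."""


class CaremapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CaremapError):
    """A required column or schema entry is missing or malformed."""


class ValidationError(CaremapError):
    """Input data violates a structural invariant of the data model."""


class FitError(CaremapError):
    """Model fitting failed (bad inputs or a divergent sampler)."""
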