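"""Exception hierarchy shared across the pipeline stages."""


class GlycassocError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GlycassocError):
    """Input does not conform to the declared panel schema."""


class ValidationError(GlycassocError):
    """Input values violate a table invariant (sign, sums, duplicates...)."""


class DegenerateDataError(GlycassocError):
    """A sample or variable is degenerate for the requested operation
    (all-zero chromatogram row, constant variable, zero trait denominator)."""


class InsufficientDataError(GlycassocError):
    """Too few complete cases to fit the requested model."""
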