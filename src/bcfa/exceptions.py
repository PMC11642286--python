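"""Exception hierarchy shared across the package."""


class BcfaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BcfaError, ValueError):
    """Input data violates a structural or range constraint."""


class DegenerateVarianceError(ValidationError):
    """A column has (numerically) zero sample variance."""


class InsufficientDataError(ValidationError):
    """Too few rows / draws for the requested computation."""


class PatternError(ValidationError):
    """A loading pattern is not a valid confirmatory structure."""


class PriorError(ValidationError):
    """A prior setting is improper or out of range."""


class MatrixValidityError(ValidationError):
    """A covariance/correlation matrix fails symmetry or positive definiteness."""
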