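"""Exception hierarchy shared across the package."""


class EthnosurveyError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EthnosurveyError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FormatError(EthnosurveyError, ValueError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(EthnosurveyError, ValueError):
    """A record violates the data model's invariants."""


class SeparationError(EthnosurveyError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit.

    Raised instead of silently returning diverging coefficients, which
    would otherwise masquerade as huge but meaningless odds ratios.
    """


class SingularMatrixError(EthnosurveyError, RuntimeError):
    """The Fisher information is singular; names the offending covariate."""
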