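"""Exception hierarchy used across the package."""


class FluoroQsprError(Exception):
    """Base class for all package errors."""


class ParseError(FluoroQsprError, ValueError):
    """A structure string could not be parsed."""


class ContributionError(FluoroQsprError, KeyError):
    """A polar atom environment has no surface-area contribution entry."""


class DomainError(FluoroQsprError, ValueError):
    """Input values violate a mathematical precondition (e.g. non-positive integral)."""


class DegenerateFitError(FluoroQsprError, RuntimeError):
    """A fit is underdetermined or the data carry no usable transition."""


class ConvergenceError(FluoroQsprError, RuntimeError):
    """A nonlinear fit failed to converge; carries a residual report."""


class TableError(FluoroQsprError, ValueError):
    """A descriptor table violates its contract (bad cell, collision, unknown id)."""


class MissingDescriptorError(FluoroQsprError, KeyError):
    """A requested compound lacks one or more descriptor values."""


class CorrelationError(FluoroQsprError, ValueError):
    """Correlation is undefined (constant input or too few points)."""
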