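"""Exception hierarchy.

All errors raised by this package derive from :class:`RatioMIError` so that
callers (in particular the simulation harness, which must count and contain
per-replicate failures) can catch them with a single except clause.
"""


class RatioMIError(Exception):
    """Base class for all errors raised by ratiomi."""


class RoleError(RatioMIError):
    """A declared column role is missing, duplicated, or inconsistent."""


class ParseError(RatioMIError):
    """A delimited file contains a cell that is neither numeric nor the
    missing-value token."""


class DomainError(RatioMIError):
    """Input values violate a domain requirement (zero denominator,
    non-positive survival time, non-positive component under a log model,
    ratio/component mismatch)."""


class ConvergenceError(RatioMIError):
    """An iterative fit failed to converge (Cox Newton-Raphson, EM)."""


class ImputationError(RatioMIError):
    """The imputation engine produced an unusable draw (degenerate P-step,
    exactly-zero imputed denominator after retry)."""
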