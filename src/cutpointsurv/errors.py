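"""Exception hierarchy.

Every error raised by this package derives from :class:`CutpointSurvError`
so callers can catch the package's failures with a single clause while the
concrete subclasses carry the diagnostic (which config field, which record,
which model term).
"""


class CutpointSurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CutpointSurvError):
    """An invalid simulation or model-selection configuration; names the field."""


class DomainError(CutpointSurvError):
    """Input outside the mathematical domain of an operation (e.g. log2 of 0)."""


class DegenerateDataError(CutpointSurvError):
    """Data carries no usable information (constant scores, empty cohort)."""


class BoundaryError(CutpointSurvError):
    """A candidate cut-point leaves one marker group empty."""


class InsufficientDataError(CutpointSurvError):
    """Too few admissible values to form a cut-point grid."""


class RankDeficiencyError(CutpointSurvError):
    """Cox design matrix not full rank on the event risk sets; names the terms."""


class ConvergenceError(CutpointSurvError):
    """Partial-likelihood maximization diverged (e.g. monotone likelihood)."""
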