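"""Exception taxonomy.

Input-validation failures raise distinct subclasses of
:class:`CohortValidationError` so callers can react to (and test for) the
specific defect; numerical/statistical preconditions raise the ``*DataError``
classes below.
"""


class CohortValidationError(ValueError):
    """Base class for malformed demographics / tract-FA inputs."""


class MissingColumnError(CohortValidationError):
    """A required column is absent from an input table."""


class UnknownCategoryError(CohortValidationError):
    """A categorical cell holds a token outside its allowed vocabulary."""


class FABoundsError(CohortValidationError):
    """A fractional-anisotropy value lies outside the open interval (0, 1)."""


class MissingValueError(CohortValidationError):
    """A required cell is empty; missing FA is rejected, never imputed."""


class IdMismatchError(CohortValidationError):
    """Demographics and tract-FA tables do not cover the same subject ids."""


class DuplicateIdError(CohortValidationError):
    """A subject id occurs more than once within one table."""


class DurationConsistencyError(CohortValidationError):
    """duration != age - onset beyond the rounding slack, or one of the
    pair is present without the other."""


class RankDeficientDesignError(ValueError):
    """The regression design matrix is rank deficient (e.g. constant age
    and constant sex)."""


class DegenerateDataError(ValueError):
    """Data degenerate for the requested statistic (zero variance,
    singular covariance, non-positive distance under a log, ...)."""


class TooFewControlsError(ValueError):
    """Not enough control subjects for leave-one-out subsampling."""


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""
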