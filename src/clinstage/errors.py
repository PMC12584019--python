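"""Exception taxonomy.

Every failure mode that a caller can act on gets its own class; all inherit
from :class:`ClinStageError` so scripts can catch the package's errors as one
family while letting programming errors propagate.
"""


class ClinStageError(Exception):
    """Base class for all clinstage errors."""


class SchemaError(ClinStageError):
    """A required column is missing or a column mapping is invalid."""


class CohortValidationError(ClinStageError):
    """A patient record violates a domain invariant (row-indexed message)."""


class ParameterError(ClinStageError):
    """Simulation or analysis parameters are out of their valid range."""


class FixtureError(ClinStageError):
    """A confusion-matrix fixture specification is internally inconsistent."""


class UndefinedMetricError(ClinStageError):
    """A diagnostic metric is undefined (e.g. no positives in the sample).

    Raised instead of returning a sentinel: subgroup steps can legitimately
    run out of one class and must be detected, not averaged over.
    """


class StagingError(ClinStageError):
    """The stepwise staging procedure cannot run on the given cohort."""


class PlanError(ClinStageError):
    """A stratification plan names an unsupported factor."""
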