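"""Exception hierarchy for csficv.

Every stage raises a subclass of :class:`CsfIcvError` so callers can catch
pipeline failures without masking programming errors.
"""


class CsfIcvError(Exception):
    """Base class for all csficv errors."""


class InvalidSpecError(CsfIcvError, ValueError):
    """A phantom/cohort/histogram specification violates its invariants."""


class ShapeError(CsfIcvError, ValueError):
    """Array geometries of two inputs do not agree."""


class InvalidTransformError(CsfIcvError, ValueError):
    """A 4x4 affine is singular or otherwise unusable."""


class InvalidRateError(CsfIcvError, ValueError):
    """A probability/rate lies outside [0, 1]."""


class DegeneratePhantomError(CsfIcvError, ValueError):
    """A tissue map contains no intracranial volume."""


class EmptyMaskError(CsfIcvError, ValueError):
    """The atlas intracranial mask selects no voxels."""


class DegenerateFitError(CsfIcvError, ValueError):
    """A mixture fit yields a non-positive intracranial volume."""


class ConstraintViolationError(CsfIcvError, ValueError):
    """The fitted component means violate the CSF < WM < GM ordering."""


class RegistrationError(CsfIcvError, RuntimeError):
    """Intensity-based registration did not converge."""

    def __init__(self, message: str, metric_value: float | None = None):
        super().__init__(message)
        self.metric_value = metric_value


class ValidationError(CsfIcvError, ValueError):
    """A patient record carries contradictory or out-of-range fields."""


class CodingError(CsfIcvError, ValueError):
    """A raw covariate value cannot be coded (e.g. unknown eTICI label)."""


class ImputationError(CsfIcvError, ValueError):
    """Imputation is impossible (e.g. a variable is 100% missing)."""


class DegenerateComparisonError(CsfIcvError, ValueError):
    """Group comparison requested with fewer than two groups."""


class SeparationError(CsfIcvError, RuntimeError):
    """Complete separation in a logistic fit."""

    def __init__(self, predictor: str):
        super().__init__(f"complete (quasi-)separation detected for predictor {predictor!r}")
        self.predictor = predictor


class RankDeficiencyError(CsfIcvError, ValueError):
    """The design matrix is rank deficient."""


class NotConvergedError(CsfIcvError, RuntimeError):
    """An operation requiring a converged fit received a non-converged one."""


class PoolingError(CsfIcvError, ValueError):
    """Fits with mismatched predictor lists cannot be pooled."""


class UndefinedAUCError(CsfIcvError, ValueError):
    """AUC requested with only one outcome class present."""


class DegenerateCovarianceError(CsfIcvError, ValueError):
    """DeLong variance of the AUC difference is zero with unequal AUCs."""


class NestingError(CsfIcvError, ValueError):
    """Likelihood-ratio test requested for non-nested models."""


class StageError(CsfIcvError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
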