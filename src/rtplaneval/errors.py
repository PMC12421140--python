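"""Exception hierarchy.

Every failure mode the pipeline can report deliberately maps to one of these
types so callers (and the CLI exit-code logic) can distinguish bad inputs
from genuinely undefined quantities.
"""


class RTPlanEvalError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RTPlanEvalError, ValueError):
    """A configuration object violates its invariants."""


class GenerationError(RTPlanEvalError, RuntimeError):
    """Synthetic anatomy or dose could not be placed on the requested grid."""


class GridMismatchError(RTPlanEvalError, ValueError):
    """Two arrays that must share one voxel grid do not."""


class EmptyMaskError(RTPlanEvalError, ValueError):
    """An operation that requires a nonempty region received an empty mask."""


class UndefinedMetricError(RTPlanEvalError, ValueError):
    """The requested metric is mathematically undefined for this input
    (e.g. Dice of two empty masks, HI with zero median dose)."""


class DegenerateTestError(RTPlanEvalError, ValueError):
    """A statistical test cannot be computed (e.g. zero-variance paired
    differences)."""


class InsufficientDataError(RTPlanEvalError, ValueError):
    """Too few observations for the requested statistic."""


class ValidationError(RTPlanEvalError, ValueError):
    """A cohort table or manifest failed completeness checks."""
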