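"""Exception hierarchy used across the package."""


class FuseAFTError(Exception):
    """Base class for all package errors."""


class DataFormatError(FuseAFTError, ValueError):
    """An input table is missing required columns or is otherwise malformed."""


class EmptyJoinError(FuseAFTError, ValueError):
    """No samples are shared between an expression and a clinical table."""


class EmptyIntersectionError(FuseAFTError, ValueError):
    """Gene alignment across cohorts (and an optional panel) left no genes."""


class NonPositiveTimeError(FuseAFTError, ValueError):
    """A survival time is zero or negative and cannot be log-transformed."""


class NotCanonicalError(FuseAFTError, ValueError):
    """An operation requiring a canonicalized (sorted) dataset got a raw one."""


class DegenerateWeightsError(FuseAFTError, ValueError):
    """All Kaplan-Meier weights are zero; weighted moments are undefined."""


class ConvexityError(FuseAFTError, ValueError):
    """A scalar MCP subproblem is non-convex (effective curvature <= 1/gamma)."""


class UndefinedDistanceError(FuseAFTError, ValueError):
    """Relative Euclidean distance requested for two all-zero vectors."""


class UndefinedConcordanceError(FuseAFTError, ValueError):
    """No usable pair exists for the concordance statistic."""


class CalibrationError(FuseAFTError, RuntimeError):
    """Censoring-rate bisection failed to bracket the target."""


class StratificationError(FuseAFTError, ValueError):
    """Too few events per cohort to build stratified CV folds."""
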