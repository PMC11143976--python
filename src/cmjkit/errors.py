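"""Exception hierarchy for the CMJ pipeline.

Every validation failure raises a distinct, named error so callers (and the
CLI) can report which stage of the analysis rejected a trial.
"""


class CmjError(Exception):
    """Base class for all pipeline errors."""


class TrialReadError(CmjError):
    """A trial file could not be parsed."""


class EmptyTrialError(TrialReadError):
    """Trial file contains no samples."""


class NonNumericDataError(TrialReadError):
    """Trial file contains non-numeric rows."""


class NonUniformSamplingError(TrialReadError):
    """Timestamps deviate from a uniform grid beyond tolerance."""


class SubjectNotStillError(CmjError):
    """Quiet-standing window is not quiet enough to establish body weight."""


class NoMovementError(CmjError):
    """No onset threshold crossing found (subject never moved)."""


class NoFlightError(CmjError):
    """No flight phase found (trial truncated before take-off)."""


class NoCountermovementError(CmjError):
    """Velocity never crosses zero upward after its minimum (aborted jump)."""


class InfeasibleProfileError(CmjError):
    """Synthetic jump parameters cannot produce a physically valid trial
    (e.g. the implied force would be negative)."""


class DegenerateDataError(CmjError):
    """Statistical input has no usable variance."""
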