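"""Exception hierarchy for case-base analyses."""


class CaseBaseError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CaseBaseError, ValueError):
    """Malformed input data or configuration."""


class EmptySampleError(CaseBaseError):
    """A case-base draw recruited no subjects at all."""


class SeparationError(CaseBaseError):
    """Complete or quasi-complete separation in the logistic fit."""


class RankDeficientError(CaseBaseError):
    """Design matrix is not of full column rank."""


class NotEstimableError(CaseBaseError):
    """Requested quantity is not estimable from the data (e.g. no diseased
    subject was recruited in the base sample, so rho and hence risks and
    relative risks are unavailable; odds ratios remain valid)."""


class SolverError(CaseBaseError):
    """Numerical failure while solving for the baseline disease odds."""
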