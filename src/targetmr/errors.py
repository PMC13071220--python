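"""Exception hierarchy for summary-statistics handling and MR estimation."""


class TargetMRError(Exception):
    """Base class for all package errors."""


class FormatError(TargetMRError):
    """A file does not conform to the documented dialect."""


class ValidationError(TargetMRError):
    """Input violates a documented invariant (e.g. duplicate variant IDs)."""


class DomainError(TargetMRError):
    """A numeric argument is outside the operation's domain."""


class EstimationError(TargetMRError):
    """An estimator's preconditions are not met (e.g. too few instruments)."""
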