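"""Exception hierarchy shared by all modules."""


class EcgBaselineError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcgBaselineError, ValueError):
    """A parameter is non-finite, out of range, or otherwise unusable."""


class ContractError(EcgBaselineError, ValueError):
    """Inputs violate a documented precondition (lengths, indices, annotations)."""


class UndefinedStatisticError(EcgBaselineError, ValueError):
    """A similarity statistic is undefined for the given inputs (e.g. constant signal)."""


class DegenerateArtifactError(EcgBaselineError, ValueError):
    """The artifact signal is identically zero and cannot be scaled to a target SNR."""


class InsufficientAnchorsError(EcgBaselineError, ValueError):
    """Fewer than four anchor points were supplied for cubic-spline baseline estimation."""
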