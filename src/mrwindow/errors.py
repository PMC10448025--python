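"""Exception and warning types shared across the package."""


class MRWindowError(Exception):
    """Base class for all package errors."""


class FormatError(MRWindowError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(MRWindowError):
    """Input data violates a domain invariant (e.g. WW <= 0)."""


class DegenerateImageError(MRWindowError):
    """An image has no voxels with intensity strictly greater than zero."""


class UnmappableImageError(MRWindowError):
    """An image's landmarks collapse to fewer than two distinct knots."""


class FrameError(MRWindowError):
    """A window was supplied in the wrong unit frame (native vs standardized)."""


class UnknownConditionError(MRWindowError):
    """A series' imaging condition is absent from the model or scale registry."""


class TrainingError(MRWindowError):
    """Standard-scale training had zero usable images."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics (split-Rhat, sWW positivity) flagged a problem."""


class ScenarioWarning(UserWarning):
    """A simulation scenario produced an unusually high rejection rate."""
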