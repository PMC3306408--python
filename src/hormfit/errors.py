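"""Exception hierarchy for hormfit.

Every error raised by the package derives from :class:`HormfitError` so
callers can catch the whole family at once (the CLI maps them to exit
codes: validation-type errors -> 3, fitting failures -> 2).
"""


class HormfitError(Exception):
    """Base class for all hormfit errors."""


# --- data / validation -------------------------------------------------

class SchemaError(HormfitError):
    """A required input column is missing or unparseable."""


class ValidationError(HormfitError):
    """An input value violates a precondition (e.g. negative dose)."""


class DesignError(HormfitError):
    """The dose design is inadequate (fewer than 5 distinct dose levels,
    missing untreated control, ...)."""


class InsufficientReplicationError(HormfitError):
    """A dose level has fewer than 2 replicates but replicate-based
    weighting was requested."""


class DegenerateVarianceError(HormfitError):
    """A dose level has zero replicate standard deviation and the
    zero-SD fallback is disabled."""


# --- model evaluation / reparameterization -----------------------------

class NumericDomainError(HormfitError):
    """A parameter or dose is outside the model's numeric domain."""


class ReparamInfeasibleError(HormfitError):
    """The defining relationship cannot be solved for the eliminated
    parameter (degenerate coefficient)."""


class StationarityDegenerateError(HormfitError):
    """The closed form for f at the stationary dose M has a vanishing
    denominator (e.g. b = 0: flat logistic term)."""


class CapabilityError(HormfitError):
    """Unsupported model-family / target combination."""


class NoHormesisError(HormfitError):
    """M or LDS requested for a curve without hormesis (f <= 0)."""


class RootNotFoundError(HormfitError):
    """No sign change found within the bracket-expansion limit."""


# --- fitting -----------------------------------------------------------

class StartValueError(HormfitError):
    """Starting values cannot be derived (e.g. no untreated control)."""


class NonConvergenceError(HormfitError):
    """All starting-value ladder steps failed; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(HormfitError):
    """J'WJ is singular at the optimum; names the non-identifiable
    parameter direction."""

    def __init__(self, message, direction=None):
        super().__init__(message)
        self.direction = direction


class NotEstimatedError(HormfitError):
    """An inference was requested for a parameter that is fixed, not
    estimated."""


# --- experiments -------------------------------------------------------

class ConfigError(HormfitError):
    """Invalid simulation or run configuration."""


class ExperimentInvalidError(HormfitError):
    """Too many fit failures to trust a Monte-Carlo experiment."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
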