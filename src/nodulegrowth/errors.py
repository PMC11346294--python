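"""Exception hierarchy shared across the package."""


class NoduleGrowthError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NoduleGrowthError, ValueError):
    """A table is missing a required column or has an unusable layout."""


class ParseError(NoduleGrowthError, ValueError):
    """A row-level value could not be interpreted (carries row context)."""


class CohortValidationError(NoduleGrowthError, ValueError):
    """A cohort or series violates a structural invariant."""


class ParameterError(NoduleGrowthError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class DomainError(NoduleGrowthError, ValueError):
    """A mathematically undefined evaluation was requested."""


class BlowUpError(DomainError):
    """A time at or beyond the finite blow-up time t* was requested (beta > 1)."""

    def __init__(self, t_star: float, message: str | None = None):
        self.t_star = t_star
        super().__init__(message or f"requested time at or beyond blow-up time t* = {t_star:.6g}")


class FitConvergenceError(NoduleGrowthError, RuntimeError):
    """A fit failed to converge or the root could not be bracketed."""


class EvaluationError(NoduleGrowthError, ValueError):
    """A classifier evaluation was requested on degenerate inputs."""
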