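"""Exception and warning hierarchy shared across the package."""


class SavReleaseError(Exception):
    """Base class for all package errors."""


class DomainError(SavReleaseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InvalidShapeError(DomainError):
    """A shape specification violates its geometric invariants."""


class InfeasibleGeometryError(SavReleaseError):
    """No dimension satisfies the requested SA/V (and/or dose) target.

    Carries ``bound``, the attainable SA/V limit for the fixed dimensions,
    when that limit has a closed form.
    """

    def __init__(self, message: str, bound: float | None = None):
        super().__init__(message)
        self.bound = bound


class InsufficientDataError(SavReleaseError):
    """Too few data points below the fit cap for the requested model."""


class ConvergenceError(SavReleaseError):
    """Nonlinear fit failed to converge after all multi-starts."""


class RankError(SavReleaseError):
    """A regression design is rank deficient (e.g. a single distinct SA/V)."""


class UndefinedMDTError(SavReleaseError):
    """MDT is undefined because the profile never releases anything."""


class StageError(SavReleaseError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the calibrated SA/V domain."""


class UnderSampledWarning(UserWarning):
    """Fewer points available than the recommended minimum (f2 rule of 12)."""


class NonMonotoneWarning(UserWarning):
    """A cumulative release profile steps backwards by more than 2 %."""


class ExcludedConstantWarning(UserWarning):
    """A non-positive fitted constant was excluded from a log-log regression."""
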