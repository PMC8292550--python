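"""Exception and warning types shared across the package."""


class InterkitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(InterkitError, ValueError):
    """A physical parameter violates its domain (e.g. non-positive rate)."""


class AlignmentError(InterkitError):
    """Time ranges of curves to be combined do not overlap."""


class ScheduleError(InterkitError):
    """Injection schedules of curves to be combined disagree."""


class SimulationError(InterkitError):
    """Numerical integration of a kinetic model failed."""


class FitError(InterkitError):
    """Global fit failed or input is degenerate.

    Carries ``best_state`` (may be None) with the best parameters reached
    before the failure, for post-mortem inspection.
    """

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state


class GenerationError(InterkitError):
    """A synthetic fixture request is geometrically or numerically infeasible."""


class IdentifiabilityWarning(UserWarning):
    """Fit input is formally valid but parameters may not be identifiable."""


class DegenerateDataWarning(UserWarning):
    """A statistic was requested on degenerate data (e.g. all-zero residuals)."""
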