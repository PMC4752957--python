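"""Exception hierarchy shared across the package."""


class FactorialVCError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FactorialVCError):
    """A required column is missing or has the wrong type."""


class ValidationError(FactorialVCError):
    """Input values violate a documented invariant (e.g. negative counts)."""


class ConfigurationError(FactorialVCError):
    """Inconsistent options (bad family/link pair, duplicate codes, ...)."""


class DesignError(FactorialVCError):
    """The mating design cannot identify the requested variance components."""


class RankError(FactorialVCError):
    """The fixed-effect design matrix is rank deficient."""


class ConvergenceError(FactorialVCError):
    """The optimizer did not converge within its iteration budget."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FitError(FactorialVCError):
    """A model fit failed for reasons other than optimizer convergence."""


class UsageError(FactorialVCError):
    """An operation was invoked on inputs it is not defined for."""


class TestError(FactorialVCError):
    """A significance test could not be completed (e.g. refits failing)."""

    def __init__(self, message, states=None):
        super().__init__(message)
        self.states = states


class PlottingError(FactorialVCError):
    """A figure could not be produced from the supplied values."""
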