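"""Exception hierarchy shared across the package."""


class PhenofluctError(Exception):
    """Base class for all package-specific errors."""


class InvalidSignalError(PhenofluctError, ValueError):
    """Nutrient signal parameters violate nonnegativity or periodicity."""


class DomainError(PhenofluctError, ValueError):
    """An argument lies outside the mathematical domain of a function."""


class AnalyticPreconditionError(PhenofluctError, ValueError):
    """An analytic module was called with zeta < gamma, where the Gaussian
    closure and the asymptotic theory do not apply."""


class StateError(PhenofluctError, ValueError):
    """A dynamical state violates its invariants (e.g. v <= 0)."""


class IntegrationError(PhenofluctError, RuntimeError):
    """The ODE integrator failed to converge."""


class StabilityError(PhenofluctError, ValueError):
    """The explicit finite-difference stability conditions are violated."""


class DivergenceError(PhenofluctError, RuntimeError):
    """The finite-difference solution produced NaN/Inf."""


class SurvivalHypothesisError(PhenofluctError, ValueError):
    """The periodic-size attractor was requested for a population whose
    invasion quantity exceeds the survival threshold (the attractor is the
    zero solution)."""


class ConfigError(PhenofluctError, ValueError):
    """An experiment configuration is malformed or inconsistent."""
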