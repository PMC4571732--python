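"""Exception hierarchy for itnevo."""


class ItnevoError(Exception):
    """Base class for all errors raised by itnevo."""


class ParameterError(ItnevoError, ValueError):
    """A model parameter violates its validity constraints."""


class ConvergenceDomainError(ItnevoError):
    """The geometric series of repeat host searches does not converge.

    Only reachable when Q*phi*r*(1-mu_r) >= 1, i.e. with parameters
    outside the validated domain.
    """


class DegenerateParametersError(ItnevoError):
    """Per-cycle survival reached 1 so the expected lifespan diverges."""


class PopulationExtinctError(ItnevoError):
    """Mean fitness is zero in at least one sex; the recursion is undefined."""


class ResidentInviableError(ItnevoError):
    """The resident genotype has zero fitness, so an invasion growth
    factor against it is undefined."""


class UndefinedRatioError(ItnevoError):
    """The larvicide-only scenario never reaches the target frequency,
    so the ITN/larvicide evolution-time ratio is undefined."""
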