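"""Exception hierarchy for the tspn package."""


class TspnError(Exception):
    """Base class for all package errors."""


class ParameterError(TspnError, ValueError):
    """Invalid model or protocol parameter."""


class DomainError(TspnError, ValueError):
    """Mathematically invalid input (non-positive concentration, zero denominator)."""


class IntegrationDivergedError(TspnError, RuntimeError):
    """Numerical integration produced a non-finite or runaway state."""

    def __init__(self, step: int, t_ms: float):
        self.step = step
        self.t_ms = t_ms
        super().__init__(
            f"integration diverged at step {step} (t = {t_ms:.1f} ms); "
            "state non-finite or |V| > 200 mV"
        )


class NotExcitableError(TspnError, RuntimeError):
    """No spike could be elicited anywhere in the search bracket."""


class BracketingError(TspnError, RuntimeError):
    """A bisection bracket does not straddle the target."""


class DetectionError(TspnError, RuntimeError):
    """A trace-feature detection criterion was never met."""


class FitError(TspnError, RuntimeError):
    """A nonlinear fit failed to converge."""
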