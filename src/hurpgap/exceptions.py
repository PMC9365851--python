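"""Exception hierarchy for hurpgap."""


class HurpGapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HurpGapError, ValueError):
    """A model or configuration parameter violates its constraints."""


class SolverDivergenceError(HurpGapError):
    """The PDE solver produced non-finite state."""


class ConvergenceError(HurpGapError):
    """Equilibration did not converge within the allowed horizon."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class UndefinedGapError(HurpGapError):
    """Gap measurement requested on a profile with no signal."""


class NormalisationError(HurpGapError):
    """FRAP double normalisation hit a zero denominator."""


class FormatError(HurpGapError):
    """A tabular input file violates the expected dialect."""


class FitError(HurpGapError):
    """A curve fit failed to converge."""


class DegenerateProposalError(HurpGapError):
    """The MCMC pilot accepted no proposals; the proposal scale is unusable."""


class InsufficientSamplesError(HurpGapError):
    """Posterior summarisation requested with no post-burn-in draws."""
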