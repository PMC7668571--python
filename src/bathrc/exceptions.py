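"""Exception hierarchy for bathrc.

All package errors derive from :class:`BathRCError` so callers (and the CLI)
can catch one base class.
"""


class BathRCError(Exception):
    """Base class for all bathrc errors."""


class InvalidParameterError(BathRCError, ValueError):
    """A physical parameter or setting violates its validity range."""


class IllPosedError(BathRCError):
    """The requested network configuration has no well-posed dynamics."""


class NumericalError(BathRCError):
    """A linear-algebra or root-finding step failed unexpectedly."""


class ConvergenceError(NumericalError):
    """An iterative computation did not converge.

    Carries the final residual so callers can diagnose step-size or
    bracketing problems.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InfeasibleTargetError(BathRCError):
    """The requested tidal volume cannot be reached by adding restriction."""

    def __init__(self, message: str, unrestricted_vt: float | None = None):
        super().__init__(message)
        self.unrestricted_vt = unrestricted_vt


class BracketExhaustedError(BathRCError):
    """Restrictor search exceeded the resistance cap without bracketing."""


class RankDeficiencyError(BathRCError):
    """A regression design matrix is rank deficient (degenerate data)."""


class EstimationError(BathRCError):
    """A parameter estimate is unreliable or physically inadmissible."""


class FormatError(BathRCError):
    """A waveform or config file does not match the expected format."""


class AlignmentError(BathRCError):
    """Two waveform records cannot be co-registered."""


class ConfigError(FormatError):
    """A parameter config file is malformed or has unknown keys."""
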