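"""Exception hierarchy for mabrsim.

All package-specific errors derive from :class:`MabrsimError` so callers can
catch everything with one clause; validation-type errors additionally derive
from ``ValueError`` and solver-type errors from ``RuntimeError``.
"""

from __future__ import annotations


class MabrsimError(Exception):
    """Base class for all mabrsim errors."""


class InvalidParameterError(MabrsimError, ValueError):
    """A model constant violates its admissibility constraints."""


class InvalidStateError(MabrsimError, ValueError):
    """A state vector (concentration, volume fraction) is inadmissible."""


class TemperatureRangeError(MabrsimError, ValueError):
    """Temperature outside the validity range of a correction law."""


class ConfigError(MabrsimError, ValueError):
    """Configuration file failed schema validation."""


class InsufficientDataError(MabrsimError, ValueError):
    """Too few data points for the requested estimate."""


class UndefinedFractionError(MabrsimError, ValueError):
    """A ratio statistic is undefined (zero denominator)."""


class FitError(MabrsimError, RuntimeError):
    """Nonlinear least squares failed to converge."""


class SolverError(MabrsimError, RuntimeError):
    """The biofilm solver failed; carries diagnostics for post-mortem.

    Attributes
    ----------
    residual : float or None
        Last residual norm of the failing solve.
    trajectory : object or None
        Convergence history (time, biomass totals, rate) when available.
    """

    def __init__(self, message, residual=None, trajectory=None):
        super().__init__(message)
        self.residual = residual
        self.trajectory = trajectory


class StepSizeError(MabrsimError, ValueError):
    """Biomass time step violates the stability/accuracy bound.

    Attributes
    ----------
    suggested_dt : float
        A step size that satisfies the bound.
    """

    def __init__(self, message, suggested_dt):
        super().__init__(message)
        self.suggested_dt = suggested_dt


class CalibrationWarning(UserWarning):
    """Calibration ended without improvement or stuck at a bound."""
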