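"""Flow-restrictor sizing.

The headline use case for dual-patient ventilation: the shared ventilator must
run at a pressure suited to the sicker patient, so the other patient's
inspiratory limb needs a deliberate series resistance to bring their tidal
volume back to target.  Tidal volume is a smooth, strictly decreasing function
of the added inspiratory resistance, so the inverse problem is solved by
bracketed bisection -- robust, derivative-free and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    BracketExhaustedError,
    ConvergenceError,
    InfeasibleTargetError,
    InvalidParameterError,
)
from .rc_core import CircuitParams, LungParams, VentSettings, cyclic_steady_state

__all__ = ["SizingResult", "vt_vs_restriction", "required_restriction"]


@dataclass(frozen=True)
class SizingResult:
    """Outcome of an inverse restrictor calculation.

    ``bracket`` is the final resistance interval that contained the answer;
    ``iterations`` counts bisection steps (bracket expansion excluded).
    """

    r_restrictor: float
    achieved_vt: float
    target_vt: float
    iterations: int
    bracket: tuple[float, float]


def _vt_at(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    r_restrictor: float,
) -> float:
    return cyclic_steady_state(
        lung, replace(circuit, r_restrictor_insp=float(r_restrictor)), settings
    ).vt


def vt_vs_restriction(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    resistance_grid,
) -> pd.DataFrame:
    """Tidal volume at each inspiratory restrictor resistance on a grid.

    Returns a DataFrame with columns ``r_restrictor`` and ``vt`` (L); ``vt``
    is non-increasing in ``r_restrictor``.
    """
    grid = np.asarray(resistance_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidParameterError("resistance grid must be a non-empty 1-D array")
    if (grid < 0).any():
        raise InvalidParameterError("resistance grid values must be >= 0")
    vts = [_vt_at(lung, circuit, settings, r) for r in grid]
    return pd.DataFrame({"r_restrictor": grid, "vt": vts})


def required_restriction(
    target_vt: float,
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    tolerance: float = 1e-4,
    r_cap: float = 1000.0,
    max_iter: int = 200,
) -> SizingResult:
    """Inspiratory restrictor resistance delivering a target tidal volume.

    Bisection on the added inspiratory resistance, with the initial bracket
    [0, 50] cmH2O/(L/s) doubled until it straddles the target.  The tolerance
    is expressed in litres because the clinically relevant quantity is the
    delivered volume, not the resistance.

    Raises
    ------
    InfeasibleTargetError
        If the target exceeds the unrestricted tidal volume (added resistance
        can only reduce volume).  The error carries the unrestricted value.
    BracketExhaustedError
        If the target is so small that the required resistance exceeds
        ``r_cap``.
    """
    if target_vt <= 0:
        raise InvalidParameterError(f"target_vt must be > 0, got {target_vt}")
    if tolerance <= 0:
        raise InvalidParameterError(f"tolerance must be > 0, got {tolerance}")
    vt0 = _vt_at(lung, circuit, settings, 0.0)
    if target_vt > vt0 + tolerance:
        raise InfeasibleTargetError(
            f"target vt {target_vt:.4f} L exceeds the unrestricted vt "
            f"{vt0:.4f} L; restriction can only reduce volume",
            unrestricted_vt=vt0,
        )
    if abs(vt0 - target_vt) <= tolerance:
        return SizingResult(0.0, vt0, target_vt, 0, (0.0, 0.0))

    lo, hi = 0.0, 50.0
    vt_hi = _vt_at(lung, circuit, settings, hi)
    while vt_hi > target_vt:
        lo, hi = hi, hi * 2.0
        if hi > r_cap:
            raise BracketExhaustedError(
                f"target vt {target_vt:.4f} L needs more than {r_cap:g} "
                f"cmH2O/(L/s) of restriction"
            )
        vt_hi = _vt_at(lung, circuit, settings, hi)

    for iteration in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        vt_mid = _vt_at(lung, circuit, settings, mid)
        if abs(vt_mid - target_vt) <= tolerance:
            return SizingResult(mid, vt_mid, target_vt, iteration, (lo, hi))
        if vt_mid > target_vt:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"bisection did not reach |vt - target| <= {tolerance:g} L in "
        f"{max_iter} iterations",
        residual=abs(vt_mid - target_vt),
    )
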