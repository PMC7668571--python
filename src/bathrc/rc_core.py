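"""Lumped resistance-compliance network model of pressure-controlled ventilation.

The ventilator circuit and patient are reduced to four lumped elements: a
series tubing resistance ``Rv`` (plus any deliberately added flow restrictor
``Rr``), a tubing compliance ``Cv`` hanging on the node between the tubing and
the patient, a patient airway resistance ``R``, and a lung compliance ``C``.
In pressure-control mode the ventilator drives this network with an ideal
square wave switching between PEEP (expiration) and PEEP + Pinsp
(inspiration).

Within each phase the network is a linear time-invariant affine system in the
state ``x = (p_tube, p_lung)`` (or just ``p_lung`` when ``Cv = 0``), so one
breath is two matrix-exponential flow maps.  The breath-to-breath periodic
solution -- the cyclic steady state -- is the fixed point of the composed
cycle map and is obtained by solving a small linear system; no time-marching
is required.  A fixed-step RK4 integrator (:func:`simulate_transient`) is
provided as an independent numerical oracle.

Units are fixed package-wide: pressures in cmH2O, volumes in L, flows in L/s,
resistances in cmH2O/(L/s), compliances in L/cmH2O, respiratory rate in
breaths/min, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .exceptions import (
    ConvergenceError,
    IllPosedError,
    InvalidParameterError,
    NumericalError,
)

Phase = Literal["insp", "exp"]

__all__ = [
    "VentSettings",
    "PhaseTiming",
    "LungParams",
    "CircuitParams",
    "PhaseSystem",
    "CycleSolution",
    "TransientResult",
    "phase_timing",
    "drive_pressure",
    "phase_dynamics",
    "cyclic_steady_state",
    "steady_state_waveforms",
    "first_order_vt",
    "simulate_transient",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VentSettings:
    """Ventilator control-panel settings for pressure-controlled ventilation.

    Parameters
    ----------
    pinsp : float
        Inspiratory pressure in excess of PEEP, cmH2O.
    peep : float
        Positive end-expiratory pressure, cmH2O.
    rr : float
        Respiratory rate, breaths per minute.
    ie_e : float
        Expiratory part ``E`` of the I:E ratio ``1:E`` (e.g. ``ie_e=2`` for
        I:E = 1:2).
    """

    pinsp: float
    peep: float
    rr: float
    ie_e: float = 2.0

    def __post_init__(self) -> None:
        if self.pinsp < 0:
            raise InvalidParameterError(f"pinsp must be >= 0, got {self.pinsp}")
        if self.peep < 0:
            raise InvalidParameterError(f"peep must be >= 0, got {self.peep}")
        if self.rr <= 0:
            raise InvalidParameterError(f"rr must be > 0, got {self.rr}")
        if self.ie_e <= 0:
            raise InvalidParameterError(
                f"I:E expiratory ratio E must be > 0, got {self.ie_e}"
            )


@dataclass(frozen=True)
class PhaseTiming:
    """Duration of the inspiratory and expiratory phases of one breath."""

    t_insp: float
    t_exp: float

    @property
    def period(self) -> float:
        return self.t_insp + self.t_exp


@dataclass(frozen=True)
class LungParams:
    """Patient airway resistance and lung compliance, optionally per phase.

    ``r`` and ``c`` are the default values; ``r_insp``/``r_exp`` and
    ``c_insp``/``c_exp`` override them during the corresponding phase, giving
    up to four parameters per patient (eight with the tubing included).
    """

    r: float
    c: float
    r_insp: float | None = None
    r_exp: float | None = None
    c_insp: float | None = None
    c_exp: float | None = None

    def __post_init__(self) -> None:
        for name in ("r", "r_insp", "r_exp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        for name in ("c", "c_insp", "c_exp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")

    def resistance(self, phase: Phase) -> float:
        override = self.r_insp if phase == "insp" else self.r_exp
        return self.r if override is None else override

    def compliance(self, phase: Phase) -> float:
        override = self.c_insp if phase == "insp" else self.c_exp
        return self.c if override is None else override


@dataclass(frozen=True)
class CircuitParams:
    """Ventilator tubing parameters and added restrictor resistances.

    ``c_v = 0`` selects the single-compliance limit (no tubing storage).  The
    restrictor contributes to the series resistance only in the phase where it
    is placed; by default both are zero and expiration sees ``r_v`` alone.
    """

    r_v: float
    c_v: float = 0.0
    r_restrictor_insp: float = 0.0
    r_restrictor_exp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_v", "c_v", "r_restrictor_insp", "r_restrictor_exp"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    def series_resistance(self, phase: Phase) -> float:
        """Total ventilator-side series resistance for a phase."""
        extra = self.r_restrictor_insp if phase == "insp" else self.r_restrictor_exp
        return self.r_v + extra


@dataclass(frozen=True)
class PhaseSystem:
    """Affine dynamics ``dx/dt = A x + b P`` of one phase at drive pressure P.

    The equilibrium of the phase is every state equal to the drive pressure,
    i.e. ``x_eq = P * ones``, which is equivalent to ``b = -A @ ones``.
    """

    a: np.ndarray
    b: np.ndarray
    states: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return self.a.shape[0]

    def equilibrium(self, p_drive: float) -> np.ndarray:
        return np.full(self.n_states, float(p_drive))

    def time_constants(self) -> np.ndarray:
        """Eigen time constants -1/lambda, sorted fastest first."""
        lam = np.linalg.eigvals(self.a)
        return np.sort(-1.0 / lam.real)


@dataclass(frozen=True)
class CycleSolution:
    """One period of the cyclic steady state, sampled on a uniform grid.

    ``vt`` is the tidal volume, ``C * (max p_lung - min p_lung)`` with the
    extrema located exactly (they fall slightly inside the phases, at the
    zero crossings of patient flow, not at the switch instants).
    """

    time: np.ndarray
    p_vent: np.ndarray
    p_tube: np.ndarray
    p_lung: np.ndarray
    q_patient: np.ndarray
    vt: float
    state0: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Waveforms as a DataFrame with the canonical column names."""
        return pd.DataFrame(
            {
                "time_s": self.time,
                "p_vent_cmH2O": self.p_vent,
                "p_tube_cmH2O": self.p_tube,
                "p_lung_cmH2O": self.p_lung,
                "q_patient_Lps": self.q_patient,
            }
        )


# ---------------------------------------------------------------------------
# Timing and drive
# ---------------------------------------------------------------------------


def phase_timing(settings: VentSettings) -> PhaseTiming:
    """Split the breath period 60/RR according to the I:E ratio 1:E."""
    period = 60.0 / settings.rr
    t_insp = period / (1.0 + settings.ie_e)
    return PhaseTiming(t_insp=t_insp, t_exp=period - t_insp)


def drive_pressure(settings: VentSettings, timing: PhaseTiming, t) -> np.ndarray:
    """Ideal square-wave ventilator pressure at time(s) ``t`` (seconds).

    Returns PEEP + Pinsp during inspiration and PEEP during expiration;
    times outside ``[0, period)`` are wrapped onto the cycle.
    """
    tc = np.mod(np.asarray(t, dtype=float), timing.period)
    out = settings.peep + settings.pinsp * (tc < timing.t_insp)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Phase dynamics
# ---------------------------------------------------------------------------


def phase_dynamics(
    lung: LungParams, circuit: CircuitParams, phase: Phase
) -> PhaseSystem:
    """Affine state-space system of one ventilation phase.

    With tubing compliance (``c_v > 0``) the state is ``(p_tube, p_lung)``:

        c_v dp_tube/dt = (P - p_tube)/R_series - (p_tube - p_lung)/r
        c   dp_lung/dt = (p_tube - p_lung)/r

    With ``c_v = 0`` the tubing node is algebraic and the system degenerates
    to the single state ``p_lung`` with time constant ``(R_series + r) c``.
    """
    if phase not in ("insp", "exp"):
        raise InvalidParameterError(f"phase must be 'insp' or 'exp', got {phase!r}")
    r = lung.resistance(phase)
    c = lung.compliance(phase)
    r_s = circuit.series_resistance(phase)
    c_v = circuit.c_v
    if r == 0:
        raise IllPosedError("zero patient resistance gives ill-posed dynamics")
    if c_v == 0:
        tau = (r_s + r) * c
        a = np.array([[-1.0 / tau]])
        b = np.array([1.0 / tau])
        return PhaseSystem(a=a, b=b, states=("p_lung",))
    if r_s == 0:
        raise IllPosedError(
            "zero series resistance with tubing compliance is ill-posed"
        )
    a = np.array(
        [
            [-(1.0 / r_s + 1.0 / r) / c_v, 1.0 / (r * c_v)],
            [1.0 / (r * c), -1.0 / (r * c)],
        ]
    )
    b = np.array([1.0 / (r_s * c_v), 0.0])
    return PhaseSystem(a=a, b=b, states=("p_tube", "p_lung"))


def _evolve(a: np.ndarray, x0: np.ndarray, xeq: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Exact phase solution x(t) = xeq + e^{A t} (x0 - xeq) on times ``ts``.

    Vectorised through the eigendecomposition; falls back to per-time expm
    when the eigenbasis is ill-conditioned (near-defective A).
    """
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    dx0 = x0 - xeq
    lam, v = np.linalg.eig(a)
    if np.linalg.cond(v) < 1e8:
        y0 = np.linalg.solve(v, dx0.astype(complex))
        modes = np.exp(np.outer(lam, ts)) * y0[:, None]
        return (v @ modes).real.T + xeq
    return np.stack([expm(a * t) @ dx0 + xeq for t in ts])


class _SteadyCycle:
    """Internal handle on the periodic solution of the switched system."""

    def __init__(self, lung: LungParams, circuit: CircuitParams, settings: VentSettings):
        self.lung = lung
        self.circuit = circuit
        self.settings = settings
        self.timing = phase_timing(settings)
        self.sys_i = phase_dynamics(lung, circuit, "insp")
        self.sys_e = phase_dynamics(lung, circuit, "exp")
        self.p_i = settings.peep + settings.pinsp
        self.p_e = settings.peep
        self.xeq_i = self.sys_i.equilibrium(self.p_i)
        self.xeq_e = self.sys_e.equilibrium(self.p_e)
        phi_i = expm(self.sys_i.a * self.timing.t_insp)
        phi_e = expm(self.sys_e.a * self.timing.t_exp)
        n = self.sys_i.n_states
        cycle_map = phi_e @ phi_i
        rhs = self.xeq_e + phi_e @ (self.xeq_i - phi_i @ self.xeq_i - self.xeq_e)
        lhs = np.eye(n) - cycle_map
        if not np.all(np.isfinite(lhs)) or np.linalg.cond(lhs) > 1e12:
            raise NumericalError("singular cycle map: phases are not strictly stable")
        self.x0 = np.linalg.solve(lhs, rhs)  # state at start of inspiration
        self.x_switch = self.xeq_i + phi_i @ (self.x0 - self.xeq_i)

    # -- evaluation ---------------------------------------------------------

    def states_at(self, times) -> tuple[np.ndarray, np.ndarray]:
        """States and inspiration mask at arbitrary times (wrapped mod period)."""
        tc = np.mod(np.atleast_1d(np.asarray(times, dtype=float)), self.timing.period)
        insp = tc < self.timing.t_insp
        out = np.empty((tc.size, self.sys_i.n_states))
        if insp.any():
            out[insp] = _evolve(self.sys_i.a, self.x0, self.xeq_i, tc[insp])
        if (~insp).any():
            out[~insp] = _evolve(
                self.sys_e.a, self.x_switch, self.xeq_e, tc[~insp] - self.timing.t_insp
            )
        return out, insp

    def waveforms(self, times) -> dict[str, np.ndarray]:
        """p_vent, p_tube, p_lung, q_patient and lung volume at given times."""
        states, insp = self.states_at(times)
        r_i = self.lung.resistance("insp")
        r_e = self.lung.resistance("exp")
        if self.sys_i.n_states == 2:
            p_tube = states[:, 0]
            p_lung = states[:, 1]
            q = np.where(insp, (p_tube - p_lung) / r_i, (p_tube - p_lung) / r_e)
        else:
            p_lung = states[:, 0]
            rs_i = self.circuit.series_resistance("insp")
            rs_e = self.circuit.series_resistance("exp")
            q = np.where(
                insp,
                (self.p_i - p_lung) / (rs_i + r_i),
                (self.p_e - p_lung) / (rs_e + r_e),
            )
            p_tube = p_lung + q * np.where(insp, r_i, r_e)
        p_vent = np.asarray(
            drive_pressure(self.settings, self.timing, np.atleast_1d(times))
        )
        pl_min, pl_max = self.lung_pressure_extrema()
        volume = self.lung.compliance("insp") * (p_lung - pl_min)
        return {
            "p_vent": p_vent,
            "p_tube": p_tube,
            "p_lung": p_lung,
            "q_patient": q,
            "volume": volume,
        }

    # -- extrema and tidal volume ------------------------------------------

    def _phase_extremum(self, sys: PhaseSystem, x_start, xeq, duration, kind) -> float:
        """Lung-pressure extremum within one phase.

        For the two-state system the lung keeps filling (emptying) briefly
        after the switch while p_tube is still above (below) p_lung; the
        extremum sits at the zero crossing of patient flow, located by root
        finding on g(t) = p_tube(t) - p_lung(t).  In the one-state limit the
        flow cannot change sign within a phase, so the extremum is at the
        phase start.
        """
        if sys.n_states == 1:
            return float(x_start[0])

        def g(t: float) -> float:
            x = _evolve(sys.a, x_start, xeq, [t])[0]
            return x[0] - x[1]

        g0 = g(0.0)
        want = 1.0 if kind == "min" else -1.0  # sign g must reach for a crossing
        if g0 == 0.0 or np.sign(g0) == want:
            return float(x_start[1])
        # coarse scan for the sign change, then refine
        grid = np.linspace(0.0, duration, 129)
        vals = np.array([g(t) for t in grid])
        idx = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
        if idx.size == 0:
            # flow never reverses in this phase; extremum at the far end
            end = _evolve(sys.a, x_start, xeq, [duration])[0]
            candidates = (float(x_start[1]), float(end[1]))
            return min(candidates) if kind == "min" else max(candidates)
        t_star = brentq(g, grid[idx[0]], grid[idx[0] + 1], xtol=1e-12)
        return float(_evolve(sys.a, x_start, xeq, [t_star])[0][1])

    def lung_pressure_extrema(self) -> tuple[float, float]:
        if np.allclose(self.x0, self.x_switch, atol=1e-12):
            p = float(self.x0[-1])
            return p, p
        pl_min = self._phase_extremum(
            self.sys_i, self.x0, self.xeq_i, self.timing.t_insp, "min"
        )
        pl_max = self._phase_extremum(
            self.sys_e, self.x_switch, self.xeq_e, self.timing.t_exp, "max"
        )
        return pl_min, pl_max

    @property
    def vt(self) -> float:
        pl_min, pl_max = self.lung_pressure_extrema()
        return self.lung.compliance("insp") * (pl_max - pl_min)


def steady_state_waveforms(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    times,
) -> dict[str, np.ndarray]:
    """Cyclic steady-state waveforms evaluated at arbitrary times.

    Returns a dict with keys ``p_vent``, ``p_tube``, ``p_lung``,
    ``q_patient`` and ``volume`` (lung volume above end-expiratory, L).
    Times are wrapped onto the breath cycle, so any span may be requested.
    """
    return _SteadyCycle(lung, circuit, settings).waveforms(times)


def cyclic_steady_state(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    samples_per_cycle: int = 1000,
) -> CycleSolution:
    """Exact periodic solution of the two-phase switched RC network.

    The per-phase flow maps are matrix exponentials and the periodicity
    condition ``x(0) = x(period)`` is a small linear fixed-point problem, so
    the solution is direct (no transient integration).  Waveforms are sampled
    on ``samples_per_cycle`` points over one period; the tidal volume is
    computed from the exactly-located lung-pressure extrema, independent of
    the grid.
    """
    if samples_per_cycle < 100:
        raise InvalidParameterError(
            f"samples_per_cycle must be >= 100, got {samples_per_cycle}"
        )
    cyc = _SteadyCycle(lung, circuit, settings)
    t = np.linspace(0.0, cyc.timing.period, samples_per_cycle, endpoint=False)
    w = cyc.waveforms(t)
    return CycleSolution(
        time=t,
        p_vent=w["p_vent"],
        p_tube=w["p_tube"],
        p_lung=w["p_lung"],
        q_patient=w["q_patient"],
        vt=cyc.vt,
        state0=cyc.x0,
    )


# ---------------------------------------------------------------------------
# Single-compliance closed form
# ---------------------------------------------------------------------------


def first_order_vt(
    lung: LungParams,
    series_resistance_insp: float,
    series_resistance_exp: float,
    settings: VentSettings,
) -> float:
    """Closed-form tidal volume of the single-compliance (Cv = 0) network.

    With per-phase time constants tau = (R_series + R) C the peak-to-peak lung
    pressure under a square-wave drive of amplitude Pinsp is

        dP_pp = Pinsp (1 - e_i)(1 - e_e) / (1 - e_i e_e),

    where ``e = exp(-t_phase / tau)``, and vt = C dP_pp.  Used as an analytic
    cross-check of the full solver in the Cv -> 0 limit.
    """
    if series_resistance_insp < 0 or series_resistance_exp < 0:
        raise InvalidParameterError("series resistances must be >= 0")
    timing = phase_timing(settings)
    tau_i = (series_resistance_insp + lung.resistance("insp")) * lung.compliance("insp")
    tau_e = (series_resistance_exp + lung.resistance("exp")) * lung.compliance("exp")
    e_i = np.exp(-timing.t_insp / tau_i)
    e_e = np.exp(-timing.t_exp / tau_e)
    return settings.pinsp * lung.compliance("insp") * (1 - e_i) * (1 - e_e) / (
        1 - e_i * e_e
    )


# ---------------------------------------------------------------------------
# Time-marching oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransientResult:
    """Output of the fixed-step time-marching integration.

    ``states`` holds the state trajectory (one row per step; columns named in
    ``state_names``), ``residual`` the final per-cycle state change (inf
    norm), and ``vt_last_cycle`` the tidal volume of the final cycle computed
    as C times the lung-pressure range over that cycle.
    """

    time: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]
    n_cycles: int
    residual: float
    vt_last_cycle: float

    @property
    def p_lung(self) -> np.ndarray:
        return self.states[:, -1]


def simulate_transient(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    initial_state: np.ndarray | None = None,
    n_cycles: int = 40,
    dt: float = 1e-3,
    tol: float = 1e-9,
) -> TransientResult:
    """Integrate the switched system with fixed-step RK4 from any start state.

    Each phase is divided into an integer number of steps no longer than
    ``dt``.  Integration stops once the change in the cycle-start state drops
    below ``tol`` (cmH2O, inf norm); if that does not happen within
    ``n_cycles`` -- including blow-up from a grossly too large ``dt`` -- a
    :class:`ConvergenceError` carrying the residual is raised.

    This integrator is deliberately independent of the matrix-exponential
    solver and serves as its numerical oracle.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if n_cycles < 1:
        raise InvalidParameterError(f"n_cycles must be >= 1, got {n_cycles}")
    timing = phase_timing(settings)
    phases = []
    for phase, duration, p_drive in (
        ("insp", timing.t_insp, settings.peep + settings.pinsp),
        ("exp", timing.t_exp, settings.peep),
    ):
        sys = phase_dynamics(lung, circuit, phase)
        nsteps = max(1, int(np.ceil(duration / dt)))
        phases.append((sys.a, sys.b * p_drive, duration / nsteps, nsteps))
    n = phases[0][0].shape[0]
    state_names = phase_dynamics(lung, circuit, "insp").states
    x = (
        np.full(n, float(settings.peep))
        if initial_state is None
        else np.asarray(initial_state, dtype=float).copy()
    )
    if x.shape != (n,):
        raise InvalidParameterError(f"initial_state must have shape ({n},)")

    times: list[float] = [0.0]
    traj: list[np.ndarray] = [x.copy()]
    t_now = 0.0
    residual = np.inf
    cycles_run = 0
    for cycle in range(n_cycles):
        x_start = x.copy()
        with np.errstate(over="ignore", invalid="ignore"):  # blow-up handled below
            for a, bp, h, nsteps in phases:
                for _ in range(nsteps):
                    k1 = a @ x + bp
                    k2 = a @ (x + 0.5 * h * k1) + bp
                    k3 = a @ (x + 0.5 * h * k2) + bp
                    k4 = a @ (x + h * k3) + bp
                    x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                    t_now += h
                    times.append(t_now)
                    traj.append(x.copy())
        cycles_run = cycle + 1
        residual = float(np.max(np.abs(x - x_start)))
        if not np.isfinite(residual):
            raise ConvergenceError(
                f"transient integration diverged (dt={dt} too large for the "
                f"fastest time constant)",
                residual=residual,
            )
        if residual < tol:
            break
    if residual >= tol:
        raise ConvergenceError(
            f"per-cycle state change {residual:.3e} cmH2O still above tol "
            f"{tol:.1e} after {cycles_run} cycles",
            residual=residual,
        )

    states = np.asarray(traj)
    steps_per_cycle = sum(p[3] for p in phases)
    last = states[-steps_per_cycle - 1 :, -1]
    vt_last = lung.compliance("insp") * (last.max() - last.min())
    return TransientResult(
        time=np.asarray(times),
        states=states,
        state_names=state_names,
        n_cycles=cycles_run,
        residual=residual,
        vt_last_cycle=float(vt_last),
    )
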