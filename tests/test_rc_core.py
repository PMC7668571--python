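"""Unit and property tests for the switched RC network solver."""

import numpy as np
import pytest

from bathrc import (
    CircuitParams,
    ConvergenceError,
    IllPosedError,
    InvalidParameterError,
    LungParams,
    VentSettings,
    cyclic_steady_state,
    drive_pressure,
    first_order_vt,
    phase_dynamics,
    phase_timing,
    simulate_transient,
    steady_state_waveforms,
)

from conftest import random_parameter_sets


class TestPhaseTiming:
    @pytest.mark.parametrize(
        "rr, e, period, t_insp",
        [(15.0, 2.0, 4.0, 4.0 / 3.0), (60.0, 1.0, 1.0, 0.5), (12.0, 3.0, 5.0, 1.25)],
    )
    def test_splits_period_by_ie_ratio(self, rr, e, period, t_insp):
        timing = phase_timing(VentSettings(pinsp=10, peep=5, rr=rr, ie_e=e))
        assert timing.period == pytest.approx(period)
        assert timing.t_insp == pytest.approx(t_insp)
        assert timing.t_insp + timing.t_exp == pytest.approx(timing.period)
        assert timing.t_insp / timing.t_exp == pytest.approx(1.0 / e)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rr=0.0),
            dict(rr=-5.0),
            dict(ie_e=0.0),  # degenerate 1:0 ratio
            dict(pinsp=-1.0),
            dict(peep=-0.1),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        base = dict(pinsp=10.0, peep=5.0, rr=15.0, ie_e=2.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            VentSettings(**base)


class TestDrivePressure:
    def test_square_wave_levels(self, settings25):
        timing = phase_timing(settings25)
        assert drive_pressure(settings25, timing, 0.5) == pytest.approx(30.0)
        assert drive_pressure(settings25, timing, 2.0) == pytest.approx(5.0)

    def test_zero_amplitude_is_constant_peep(self):
        s = VentSettings(pinsp=0.0, peep=5.0, rr=15.0, ie_e=2.0)
        t = np.linspace(0, 4, 100)
        assert np.all(drive_pressure(s, phase_timing(s), t) == 5.0)

    def test_wraps_onto_cycle(self, settings25):
        timing = phase_timing(settings25)
        t = np.array([0.0, 4.0, 8.5, 6.0])
        np.testing.assert_allclose(
            drive_pressure(settings25, timing, t), [30.0, 30.0, 30.0, 5.0]
        )


class TestPhaseDynamics:
    def test_two_state_slow_time_constant(self, lung1, tubing):
        # eigen-decomposition of the 2x2 state matrix for the unrestricted
        # high-pressure configuration; cross-checked against integration
        sys = phase_dynamics(lung1, tubing, "insp")
        taus = sys.time_constants()
        assert taus[-1] == pytest.approx(1.4182, abs=1e-3)

    def test_equilibrium_is_drive_pressure(self, lung1, tubing):
        sys = phase_dynamics(lung1, tubing, "insp")
        ones = np.ones(sys.n_states)
        np.testing.assert_allclose(sys.a @ ones + sys.b, 0.0, atol=1e-12)

    def test_single_state_limit_time_constant(self, lung1):
        sys = phase_dynamics(lung1, CircuitParams(r_v=22.0, c_v=0.0), "insp")
        assert sys.n_states == 1
        assert sys.time_constants()[0] == pytest.approx((22 + 12) * 0.040)

    def test_restrictor_adds_in_series(self, lung1):
        circuit = CircuitParams(r_v=22.0, c_v=0.004, r_restrictor_insp=12.0)
        assert circuit.series_resistance("insp") == 34.0
        assert circuit.series_resistance("exp") == 22.0
        sys = phase_dynamics(lung1, circuit, "insp")
        # drive enters through the total series resistance
        assert sys.b[0] == pytest.approx(1.0 / (34.0 * 0.004))

    def test_zero_patient_resistance_ill_posed(self):
        lung = LungParams(r=0.0, c=0.04)
        with pytest.raises(IllPosedError):
            phase_dynamics(lung, CircuitParams(r_v=22.0, c_v=0.0), "insp")
        with pytest.raises(IllPosedError):
            phase_dynamics(lung, CircuitParams(r_v=22.0, c_v=0.004), "insp")


class TestCyclicSteadyState:
    def test_periodic_and_bounded(self, lung1, tubing, settings25):
        sol = cyclic_steady_state(lung1, tubing, settings25)
        w = steady_state_waveforms(lung1, tubing, settings25, [0.0, 4.0])
        # state at t=0 equals state at t=period
        for key in ("p_tube", "p_lung"):
            assert abs(w[key][0] - w[key][1]) < 1e-9
        assert 0.0 <= sol.vt <= settings25.pinsp * lung1.c
        # pressures stay between PEEP and PEEP + Pinsp at steady state
        assert sol.p_lung.min() >= settings25.peep - 1e-9
        assert sol.p_lung.max() <= settings25.peep + settings25.pinsp + 1e-9

    def test_zero_drive_gives_zero_volume(self, lung1, tubing):
        s = VentSettings(pinsp=0.0, peep=5.0, rr=15.0, ie_e=2.0)
        sol = cyclic_steady_state(lung1, tubing, s)
        assert sol.vt == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sol.p_lung, 5.0, atol=1e-9)
        np.testing.assert_allclose(sol.p_tube, 5.0, atol=1e-9)

    def test_single_compliance_limit_matches_closed_form(self, lung1, settings25):
        circuit = CircuitParams(r_v=22.0, c_v=0.0)
        sol = cyclic_steady_state(lung1, circuit, settings25)
        vt_closed = first_order_vt(lung1, 22.0, 22.0, settings25)
        assert abs(sol.vt - vt_closed) < 1e-9

    def test_vt_equals_integral_of_positive_flow(self, lung1, tubing, settings25):
        # patient flow is continuous across the switches, so a fine trapezoid
        # of its positive part must recover C * peak-to-peak lung pressure
        sol = cyclic_steady_state(lung1, tubing, settings25)
        t = np.linspace(0.0, 4.0, 200_001)
        w = steady_state_waveforms(lung1, tubing, settings25, t)
        inhaled = np.trapezoid(np.clip(w["q_patient"], 0.0, None), t)
        assert inhaled == pytest.approx(sol.vt, abs=1e-6)

    def test_volume_conservation_through_series_resistance(
        self, lung1, tubing, settings25
    ):
        # over one steady cycle the net volume delivered through the tubing
        # is zero: everything inhaled is exhaled again
        t = np.linspace(0.0, 4.0, 200_001)
        w = steady_state_waveforms(lung1, tubing, settings25, t)
        r_s = np.where(t % 4.0 < 4.0 / 3.0, 22.0, 22.0)
        q_series = (w["p_vent"] - w["p_tube"]) / r_s
        assert abs(np.trapezoid(q_series, t)) < 1e-4

    def test_lung_extrema_lie_inside_the_phases(self, lung1, tubing, settings25):
        # the lung keeps filling briefly after the switch to expiration, so
        # the tidal volume exceeds the naive end-of-phase state difference
        sol = cyclic_steady_state(lung1, tubing, settings25)
        w = steady_state_waveforms(
            lung1, tubing, settings25, [0.0, phase_timing(settings25).t_insp]
        )
        naive = lung1.c * (w["p_lung"][1] - w["p_lung"][0])
        assert sol.vt > naive

    def test_rejects_coarse_sampling(self, lung1, tubing, settings25):
        with pytest.raises(InvalidParameterError):
            cyclic_steady_state(lung1, tubing, settings25, samples_per_cycle=10)

    @pytest.mark.parametrize("r_grid", [np.linspace(0, 100, 11)])
    def test_vt_monotone_in_restriction(self, lung1, tubing, settings25, r_grid):
        from dataclasses import replace

        vts = [
            cyclic_steady_state(
                lung1, replace(tubing, r_restrictor_insp=float(r)), settings25
            ).vt
            for r in r_grid
        ]
        assert np.all(np.diff(vts) < 0)

    def test_vt_monotone_in_compliance(self, tubing, settings25):
        vts = [
            cyclic_steady_state(LungParams(r=12.0, c=c), tubing, settings25).vt
            for c in np.linspace(0.01, 0.08, 8)
        ]
        assert np.all(np.diff(vts) > 0)


class TestFirstOrderVt:
    def test_reference_value(self, lung1, settings25):
        # tau = (22 + 12) * 0.040 = 1.36 s in both phases
        assert first_order_vt(lung1, 22.0, 22.0, settings25) == pytest.approx(
            0.5668, abs=2e-4
        )

    def test_zero_drive(self, lung1):
        s = VentSettings(pinsp=0.0, peep=5.0, rr=15.0, ie_e=2.0)
        assert first_order_vt(lung1, 22.0, 22.0, s) == 0.0

    def test_full_equilibration_limit(self, lung1):
        # very slow breathing: both phases fully equilibrate and
        # vt -> Pinsp * C = 1.0 L for lung 1 at Pinsp 25
        s = VentSettings(pinsp=25.0, peep=5.0, rr=0.01, ie_e=1.0)
        assert first_order_vt(lung1, 22.0, 22.0, s) == pytest.approx(1.0, abs=1e-6)


class TestTransientOracle:
    def test_matches_cyclic_solution(self, lung1, tubing, settings25):
        sol = cyclic_steady_state(lung1, tubing, settings25)
        tr = simulate_transient(lung1, tubing, settings25, dt=1e-3, tol=1e-9)
        assert abs(tr.vt_last_cycle - sol.vt) < 1e-4
        assert tr.residual < 1e-9

    def test_steady_start_is_immediately_periodic(self, lung1, tubing, settings25):
        sol = cyclic_steady_state(lung1, tubing, settings25)
        tr = simulate_transient(
            lung1, tubing, settings25, initial_state=sol.state0, dt=1e-3, tol=1e-5
        )
        assert tr.n_cycles == 1

    def test_unstable_step_flagged(self, lung1, tubing, settings25):
        # dt far above the fast time constant (~0.03 s) blows RK4 up
        with pytest.raises(ConvergenceError):
            simulate_transient(lung1, tubing, settings25, dt=0.3, n_cycles=10)

    def test_nonconvergence_reports_residual(self, lung1, tubing, settings25):
        with pytest.raises(ConvergenceError) as err:
            simulate_transient(lung1, tubing, settings25, dt=1e-3, n_cycles=1)
        assert err.value.residual is not None and err.value.residual > 0


def test_oracle_equivalence_over_random_parameters():
    """Closed-form cyclic solution vs independent RK4 time-marching."""
    for settings, lung, circuit in random_parameter_sets(8, seed=20):
        sol = cyclic_steady_state(lung, circuit, settings)
        tau_fast = phase_dynamics(lung, circuit, "insp").time_constants()[0]
        dt = min(1e-3, tau_fast / 10.0)
        tr = simulate_transient(
            lung, circuit, settings, dt=dt, tol=1e-8, n_cycles=200
        )
        assert abs(tr.vt_last_cycle - sol.vt) < 1e-4


def test_limit_equivalence_over_random_parameters():
    """Cv = 0 cyclic solution equals the first-order closed form exactly."""
    for settings, lung, circuit in random_parameter_sets(10, seed=7):
        circuit0 = CircuitParams(
            r_v=circuit.r_v,
            c_v=0.0,
            r_restrictor_insp=circuit.r_restrictor_insp,
        )
        vt_solver = cyclic_steady_state(lung, circuit0, settings).vt
        vt_closed = first_order_vt(
            lung,
            circuit0.series_resistance("insp"),
            circuit0.series_resistance("exp"),
            settings,
        )
        assert abs(vt_solver - vt_closed) < 1e-9
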