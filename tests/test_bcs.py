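"""Cardiac boundary conditions: waveform, valve schedule, Windkessel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from aortaflow import bcs
from aortaflow.bcs import (CycleWaveform, InletCondition, ValvePhase,
                           ValveSchedule, ValveSpec, WaveShape,
                           WindkesselParams, WindkesselState, goa_from_valve,
                           inlet_condition_at, make_waveform, wk2_advance,
                           wk2_steady_pressure)
from aortaflow.geometry import ParameterError


class TestWaveform:
    def test_reference_cycle_numbers(self):
        wf = make_waveform(70.0, 73_500.0, 0.35, WaveShape.HALF_SINE)
        assert wf.period == pytest.approx(60.0 / 70.0)
        vol, _ = quad(wf.inlet_flux, 0.0, wf.systole_duration, limit=200)
        assert vol == pytest.approx(73_500.0, rel=1e-3)

    @pytest.mark.parametrize("shape", [WaveShape.HALF_SINE,
                                       WaveShape.TRAPEZOID])
    def test_flux_integral_equals_stroke_volume(self, shape):
        wf = make_waveform(62.0, 80_000.0, 0.30, shape)
        vol, _ = quad(wf.inlet_flux, 0.0, wf.period, limit=400)
        assert vol == pytest.approx(80_000.0, rel=1e-3)

    def test_half_sine_peak_closed_form(self):
        """Peak flux pi/2 * SV / Ts, checked against numeric quadrature."""
        wf = make_waveform(70.0, 73_500.0, 0.35)
        ts = wf.systole_duration
        assert wf.peak_flux == pytest.approx(0.5 * math.pi * 73_500.0 / ts)
        t = np.linspace(0, ts, 10_001)
        q = wf.inlet_flux(t)
        assert q.max() == pytest.approx(wf.peak_flux, rel=1e-6)
        assert np.trapezoid(q, t) == pytest.approx(73_500.0, rel=1e-4)

    def test_flux_zero_in_diastole_nonnegative_in_systole(self):
        wf = make_waveform(70.0, 73_500.0, 0.35)
        t = np.linspace(0, 3 * wf.period, 4001)
        q = wf.inlet_flux(t)
        assert np.all(q >= 0.0)
        assert np.all(q[~wf.in_systole(t)] == 0.0)

    @given(hr=st.floats(40, 120), sv=st.floats(40e3, 120e3),
           frac=st.floats(0.21, 0.49))
    @settings(max_examples=25, deadline=None)
    def test_periodicity_property(self, hr, sv, frac):
        wf = make_waveform(hr, sv, frac)
        # sample off the phase-switch instants: the open/closed boundary is a
        # genuine discontinuity where t and t+T may round to opposite sides
        t = (np.arange(150) + 0.318) * (wf.period / 97.0)
        for f in (wf.inlet_flux, wf.coronary_flux,
                  wf.diastolic_inlet_pressure):
            assert np.allclose(f(t), f(t + wf.period), rtol=1e-12, atol=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ParameterError):
            make_waveform(70.0, 0.0, 0.35)
        with pytest.raises(ParameterError):
            make_waveform(70.0, 73_500.0, 0.6)
        with pytest.raises(ParameterError):
            make_waveform(70.0, 73_500.0, 0.1)

    def test_coronary_draw_is_four_pct_of_output(self):
        wf = make_waveform(70.0, 73_500.0, 0.35)
        vol, _ = quad(wf.coronary_flux, 0.0, wf.period, limit=400)
        assert vol == pytest.approx(0.04 * 73_500.0, rel=1e-6)


class TestValve:
    @pytest.mark.parametrize("d,goa", [(23.0, 17.0), (29.0, 23.0)])
    def test_goa_rule(self, d, goa):
        assert goa_from_valve(d) == goa
        assert ValveSpec(d).goa_diameter == goa

    def test_goa_degenerate(self):
        with pytest.raises(ParameterError):
            goa_from_valve(6.0)

    def test_schedule_open_exactly_in_systole(self):
        wf = make_waveform(70.0, 73_500.0, 0.35)
        sched = wf.schedule()
        ts = wf.systole_duration
        assert sched.state(0.0) is ValvePhase.OPEN
        assert sched.state(0.5 * ts) is ValvePhase.OPEN
        assert sched.state(ts) is ValvePhase.CLOSED        # closed at t_close
        assert sched.state(0.9 * wf.period) is ValvePhase.CLOSED
        assert sched.state(wf.period) is ValvePhase.OPEN   # next cycle

    def test_inlet_condition_kind_flips_with_schedule(self):
        wf = make_waveform(70.0, 73_500.0, 0.35)
        sched = wf.schedule()
        ts = wf.systole_duration
        c = inlet_condition_at(0.4 * ts, wf, sched)
        assert c.kind == "flux" and c.value == pytest.approx(
            float(wf.inlet_flux(0.4 * ts)))
        c = inlet_condition_at(ts, wf, sched)
        assert c.kind == "pressure"
        c = inlet_condition_at(0.8 * wf.period, wf, sched)
        assert c.kind == "pressure" and c.value == pytest.approx(
            float(wf.diastolic_inlet_pressure(0.8 * wf.period)))


class TestWindkessel:
    params = WindkesselParams()   # R = 0.121, C = 9.37

    def test_printed_time_constant(self):
        assert self.params.tau == pytest.approx(0.121 * 9.37)

    def test_equilibrium_is_fixed_point(self):
        q = 50_000.0
        st_ = WindkesselState(pressure=q * 0.121)
        for _ in range(50):
            st_ = wk2_advance(st_, q, 1e-3, self.params)
        assert st_.pressure == pytest.approx(q * 0.121, rel=1e-12)

    def test_constant_inflow_matches_analytic(self):
        """P(t) = QR + (P0 - QR) exp(-t/RC), from P0 = 0."""
        q, dt = 80_000.0, 1e-3
        st_ = WindkesselState(pressure=0.0)
        t = 0.0
        while t < 2.0:
            st_ = wk2_advance(st_, q, dt, self.params)
            t = st_.time
            exact = q * 0.121 * (1.0 - math.exp(-t / self.params.tau))
            assert abs(st_.pressure - exact) / (q * 0.121) < 1e-12

    def test_zero_inflow_exponential_decay(self):
        st_ = WindkesselState(pressure=10_000.0)
        for _ in range(100):
            st_ = wk2_advance(st_, 0.0, 5e-3, self.params)
        assert st_.pressure == pytest.approx(
            10_000.0 * math.exp(-st_.time / self.params.tau), rel=1e-12)

    def test_varying_inflow_second_order(self):
        """Halving dt reduces the error against an ODE-solver reference by
        at least a factor of two (mid-step flux sampling is second order)."""
        wf = make_waveform(70.0, 73_500.0, 0.35)
        T = wf.period

        def reference():
            sol = solve_ivp(
                lambda t, p: (float(wf.inlet_flux(t)) - p / 0.121) / 9.37,
                (0.0, T), [8_000.0], rtol=1e-11, atol=1e-8, dense_output=True)
            return sol.y[0, -1]

        ref = reference()
        errs = []
        for n in (200, 400, 800):
            dt = T / n
            st_ = WindkesselState(pressure=8_000.0)
            for k in range(n):
                q = float(wf.inlet_flux((k + 0.5) * dt))
                st_ = wk2_advance(st_, q, dt, self.params)
            errs.append(abs(st_.pressure - ref))
        assert errs[0] > 2.0 * errs[1] > 4.0 * errs[2]

    def test_mean_pressure_equals_mean_flow_times_r(self):
        """Over a converged cycle the WK2 mean pressure is R x mean flow."""
        wf = make_waveform(70.0, 73_500.0, 0.35)
        dt = wf.period / 1000
        st_ = WindkesselState(pressure=wk2_steady_pressure(
            wf.mean_cardiac_output, self.params))
        # run several cycles to settle, then average one cycle
        for k in range(5000):
            st_ = wk2_advance(st_, float(wf.inlet_flux((k + 0.5) * dt)), dt,
                              self.params)
        acc = []
        for k in range(5000, 6000):
            st_ = wk2_advance(st_, float(wf.inlet_flux((k + 0.5) * dt)), dt,
                              self.params)
            acc.append(st_.pressure)
        mean_p = np.mean(acc)
        assert mean_p == pytest.approx(
            wf.mean_cardiac_output * 0.121, rel=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            WindkesselParams(resistance=-1.0)
        with pytest.raises(ParameterError):
            wk2_advance(WindkesselState(0.0), 1.0, -1e-3, self.params)


def test_planar_flux_factor_preserves_mean_velocity():
    d = 23.0
    area = math.pi * d ** 2 / 4.0
    q3 = 123_456.0
    assert q3 * bcs.planar_flux_factor(d) / d == pytest.approx(q3 / area)


def test_waveform_trace_export_columns():
    wf = make_waveform(70.0, 73_500.0, 0.35)
    df = bcs.waveform_trace(wf, WindkesselParams(), n_per_cycle=50, cycles=2)
    assert list(df.columns) == ["t", "Q_in", "P_inlet", "Q_cor", "P_wk"]
    assert len(df) == 101
    assert (df["P_wk"] > 0).all()
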