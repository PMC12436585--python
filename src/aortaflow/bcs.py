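"""Periodic cardiac boundary-condition suite.

Systole drives a prescribed inlet flux (the valve orifice is open); diastole
closes the orifice plane and prescribes a left-ventricular filling pressure at
the inlet.  The ascending-aorta outlet is coupled to a two-element Windkessel
(resistance 0.121 Pa·s/mm^3, compliance 9.37 mm^3/Pa), and a volumetric flux
is withdrawn at the coronary ostia during diastole.

Units: mm-g-s (flux mm^3/s, pressure Pa).  Default cycle: 70 bpm with a
73.5 mL (73 500 mm^3) stroke volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .geometry import ParameterError

MMHG_PA = 133.322


class WaveShape(str, Enum):
    HALF_SINE = "half_sine"
    TRAPEZOID = "trapezoid"


class ValvePhase(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


def goa_from_valve(implanted_internal_diameter: float) -> float:
    """Geometric orifice diameter: 6.0 mm below the valve's internal diameter."""
    if implanted_internal_diameter <= 6.0:
        raise ParameterError(
            f"implanted valve internal diameter must exceed 6.0 mm, got "
            f"{implanted_internal_diameter}")
    return implanted_internal_diameter - 6.0


@dataclass(frozen=True)
class ValveSpec:
    """Orifice-plane model of an implanted valve."""

    implanted_internal_diameter: float
    goa_diameter: float = None
    valve_plane_offset: float = 0.0

    def __post_init__(self):
        if self.goa_diameter is None:
            object.__setattr__(self, "goa_diameter",
                               goa_from_valve(self.implanted_internal_diameter))
        if self.goa_diameter <= 0:
            raise ParameterError("geometric orifice diameter must be positive")

    @property
    def goa_area(self) -> float:
        return 0.25 * math.pi * self.goa_diameter ** 2


@dataclass(frozen=True)
class CycleWaveform:
    """Periodic inlet/coronary schedule for one cardiac cycle.

    ``inlet_flux`` integrates to the stroke volume over systole and vanishes
    in diastole; ``diastolic_inlet_pressure`` ramps linearly between the two
    configured LV filling pressures; the coronary flux is a constant fraction
    of mean cardiac output drawn during diastole only, split equally between
    the two ostia.
    """

    heart_rate: float = 70.0                  # bpm
    stroke_volume: float = 73_500.0           # mm^3
    systolic_fraction: float = 0.35
    shape: WaveShape = WaveShape.HALF_SINE
    diastolic_pressure_start: float = 8.0 * MMHG_PA   # Pa
    diastolic_pressure_end: float = 12.0 * MMHG_PA    # Pa
    coronary_fraction: float = 0.04           # of mean cardiac output

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be positive")
        if self.stroke_volume <= 0:
            raise ParameterError("stroke_volume must be positive")
        if not (0.2 < self.systolic_fraction < 0.5):
            raise ParameterError(
                f"systolic_fraction must lie in (0.2, 0.5), got "
                f"{self.systolic_fraction}")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def systole_duration(self) -> float:
        return self.systolic_fraction * self.period

    @property
    def mean_cardiac_output(self) -> float:
        return self.stroke_volume / self.period

    @property
    def peak_flux(self) -> float:
        ts = self.systole_duration
        if self.shape is WaveShape.HALF_SINE:
            return 0.5 * math.pi * self.stroke_volume / ts
        return self.stroke_volume / (0.8 * ts)   # 20/60/20 trapezoid

    def cycle_time(self, t):
        return np.mod(np.asarray(t, dtype=float), self.period)

    def in_systole(self, t):
        """Open-valve window: [0, Ts); exactly t = Ts counts as diastole."""
        return self.cycle_time(t) < self.systole_duration

    def inlet_flux(self, t):
        tc = self.cycle_time(t)
        ts = self.systole_duration
        s = tc / ts
        if self.shape is WaveShape.HALF_SINE:
            q = self.peak_flux * np.sin(np.pi * np.clip(s, 0.0, 1.0))
        else:
            up = np.clip(s / 0.2, 0.0, 1.0)
            down = np.clip((1.0 - s) / 0.2, 0.0, 1.0)
            q = self.peak_flux * np.minimum(up, down)
        return np.where(tc < ts, q, 0.0)

    def diastolic_inlet_pressure(self, t):
        tc = self.cycle_time(t)
        ts = self.systole_duration
        s = np.clip((tc - ts) / (self.period - ts), 0.0, 1.0)
        return self.diastolic_pressure_start + s * (
            self.diastolic_pressure_end - self.diastolic_pressure_start)

    def coronary_flux(self, t):
        """Total coronary withdrawal (both ostia), diastole only."""
        q_dia = self.coronary_fraction * self.mean_cardiac_output \
            / (1.0 - self.systolic_fraction)
        return np.where(self.in_systole(t), 0.0, q_dia)

    def schedule(self) -> "ValveSchedule":
        return ValveSchedule(period=self.period,
                             open_interval=(0.0, self.systole_duration))

    def scaled(self, flux_factor: float) -> "CycleWaveform":
        """Waveform with all fluxes scaled (e.g. to per-unit-thickness 2-D)."""
        return replace(self, stroke_volume=self.stroke_volume * flux_factor)


def make_waveform(heart_rate: float, stroke_volume: float,
                  systolic_fraction: float = 0.35,
                  shape: WaveShape = WaveShape.HALF_SINE,
                  **kwargs) -> CycleWaveform:
    """Build the cycle waveform; the systolic flux integral equals the stroke
    volume by construction (both profile shapes are normalized closed-form)."""
    return CycleWaveform(heart_rate=heart_rate, stroke_volume=stroke_volume,
                         systolic_fraction=systolic_fraction,
                         shape=WaveShape(shape), **kwargs)


@dataclass(frozen=True)
class ValveSchedule:
    """Instantaneous orifice-plane switching at the systole boundaries.

    The open interval is half-open, [t_open, t_close): at exactly t_close the
    valve is CLOSED (pressure condition), mirroring end-of-systole closure.
    """

    period: float
    open_interval: tuple

    def state(self, t) -> ValvePhase:
        tc = np.mod(t, self.period)
        t0, t1 = self.open_interval
        return ValvePhase.OPEN if (t0 <= tc < t1) else ValvePhase.CLOSED


@dataclass(frozen=True)
class WindkesselParams:
    """Two-element Windkessel: C dP/dt = Q - P/R."""

    resistance: float = 0.121      # Pa·s/mm^3
    compliance: float = 9.37       # mm^3/Pa

    def __post_init__(self):
        if self.resistance <= 0 or self.compliance <= 0:
            raise ParameterError("Windkessel R and C must be positive")

    @property
    def tau(self) -> float:
        return self.resistance * self.compliance


@dataclass
class WindkesselState:
    pressure: float      # Pa
    time: float = 0.0


def wk2_advance(state: WindkesselState, Q: float, dt: float,
                params: WindkesselParams) -> WindkesselState:
    """One step of the WK2 ODE with the flux held at Q over the step.

    Uses the exact exponential propagator of the linear ODE, so it is
    unconditionally stable, preserves the P = QR equilibrium exactly, and is
    exact for constant inflow; for time-varying Q (sampled mid-step by the
    caller) it is second-order accurate.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    decay = math.exp(-dt / params.tau)
    p_inf = Q * params.resistance
    return WindkesselState(pressure=p_inf + (state.pressure - p_inf) * decay,
                           time=state.time + dt)


def wk2_steady_pressure(mean_flow: float, params: WindkesselParams) -> float:
    """Cycle-averaged equilibrium pressure, used to initialize the outlet."""
    return mean_flow * params.resistance


@dataclass(frozen=True)
class InletCondition:
    kind: str            # "flux" | "pressure"
    value: float


def inlet_condition_at(t: float, waveform: CycleWaveform,
                       schedule: ValveSchedule) -> InletCondition:
    """Inlet boundary condition at time t: a flux while the valve is open,
    the LV filling pressure once it closes (closed at exactly t_close)."""
    if t < 0:
        raise ParameterError("t must be nonnegative")
    if schedule.state(t) is ValvePhase.OPEN:
        return InletCondition("flux", float(waveform.inlet_flux(t)))
    return InletCondition("pressure", float(waveform.diastolic_inlet_pressure(t)))


def planar_flux_factor(diameter: float) -> float:
    """Volumetric-to-planar flux conversion for 2-D (unit-thickness) runs.

    A disc of the given diameter maps to a channel of the same width; scaling
    fluxes by width/area = 4/(pi d) preserves the mean velocity.
    """
    return 4.0 / (math.pi * diameter)


def waveform_trace(waveform: CycleWaveform, wk: WindkesselParams,
                   n_per_cycle: int = 200, cycles: int = 3):
    """Sampled traces (t, Q_in, P_inlet, Q_cor, P_wk) over the given cycles,
    with the Windkessel driven by the net aortic flux. Returns a DataFrame."""
    import pandas as pd

    dt = waveform.period / n_per_cycle
    t = np.arange(cycles * n_per_cycle + 1) * dt
    state = WindkesselState(
        pressure=wk2_steady_pressure(waveform.mean_cardiac_output, wk))
    p_wk = [state.pressure]
    for tk in t[:-1]:
        q = float(waveform.inlet_flux(tk + 0.5 * dt)
                  - waveform.coronary_flux(tk + 0.5 * dt))
        state = wk2_advance(state, q, dt, wk)
        p_wk.append(state.pressure)
    return pd.DataFrame({
        "t": t,
        "Q_in": waveform.inlet_flux(t),
        "P_inlet": waveform.diastolic_inlet_pressure(t),
        "Q_cor": waveform.coronary_flux(t),
        "P_wk": np.array(p_wk),
    })
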