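"""Chest-compression waveforms and single-compartment lung mechanics.

The respiratory system is a linear one-compartment R–C model:

    dV/dt = (P_aw - P_alv) / R,      P_alv = V/C + P_pl

with airway resistance ``R`` (mbar·s/ml), compliance ``C`` (ml/mbar), volume
``V`` above FRC (ml) and pleural pressure ``P_pl`` (mbar) imposed by the
chest-compression device.  Mechanical compressions raise pleural pressure
periodically; the ventilator acts at the airway opening, either commanding a
pressure (CCSV, passive expiration) or a flow (IPPV inspiration).

During expiration the circuit is open to PEEP through the expiratory valve,
modelled as an extra series resistance; the proximal pressure sensor sits
between valve and airway resistance, so compressions produce a visible
airway-pressure excursion during expiration — the signal the CCSV inverse
trigger detects.

Integration is an explicit fixed-step scheme using the exact discretization
of the linear ODE over each step (inputs held constant within a step), so a
constant-pressure step response reproduces the closed-form exponential to
machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .ventilator_modes import (
    CCSVController,
    CCSVPreset,
    IPPVController,
    IPPVSettings,
    TriggerConfig,
)

__all__ = [
    "CompressionProfile",
    "LungParams",
    "PressureSeries",
    "LungState",
    "Event",
    "SimulationResult",
    "generate_compression_waveform",
    "step_lung",
    "simulate",
]


class CompressionProfile(BaseModel):
    """Mechanical chest-compression driver.

    ``pleural_amplitude`` is the peak pleural-pressure rise per compression in
    mbar — a free parameter of the model, since the pleural excursion produced
    by a piston device is not directly observable.  The default trapezoid
    waveform ramps up over ``rise_time`` seconds, holds, and ramps down at the
    end of the compression phase (``duty_fraction`` of the cycle).
    """

    model_config = ConfigDict(extra="forbid")

    rate: float = 100.0  # compressions/min
    duty_fraction: float = 0.5
    pleural_amplitude: float = 15.0  # mbar
    waveform_shape: Literal["trapezoid", "half_sine"] = "trapezoid"
    start_time: float = 0.0  # s
    rise_time: float = 0.05  # s, trapezoid ramp

    @model_validator(mode="after")
    def _check(self) -> "CompressionProfile":
        if self.rate <= 0:
            raise ValueError("compression rate must be positive")
        if not 0.0 < self.duty_fraction < 1.0:
            raise ValueError("duty_fraction must lie in (0, 1)")
        if self.pleural_amplitude < 0:
            raise ValueError("pleural_amplitude must be non-negative")
        if self.rise_time < 0:
            raise ValueError("rise_time must be non-negative")
        return self

    @property
    def period(self) -> float:
        return 60.0 / self.rate

    def onsets(self, duration: float) -> np.ndarray:
        """Compression-onset times within ``[0, duration)``, seconds."""
        if duration <= 0:
            return np.empty(0)
        n = int(math.ceil((duration - self.start_time) / self.period))
        t = self.start_time + self.period * np.arange(max(n, 0))
        return t[(t >= 0) & (t < duration)]


class LungParams(BaseModel):
    """Linear respiratory-mechanics constants.

    Defaults are plausible adult-pig magnitudes: compliance 25 ml/mbar,
    airway resistance 0.02 mbar·s/ml.  ``valve_resistance`` is the expiratory
    valve/circuit resistance in series during expiration; it sets how much of
    the compression-induced alveolar pressure excursion appears at the
    proximal sensor while the circuit is open to PEEP.
    """

    model_config = ConfigDict(extra="forbid")

    compliance: float = 25.0  # ml/mbar
    resistance: float = 0.02  # mbar·s/ml
    frc: float = 1000.0  # ml, resting volume
    valve_resistance: float = 0.02  # mbar·s/ml

    @model_validator(mode="after")
    def _check(self) -> "LungParams":
        if self.compliance <= 0 or self.resistance <= 0:
            raise ValueError("compliance and resistance must be positive")
        if self.frc < 0 or self.valve_resistance < 0:
            raise ValueError("frc and valve_resistance must be non-negative")
        return self


@dataclass
class PressureSeries:
    """Uniformly sampled time series (airway/vascular pressure, flow or volume)."""

    values: np.ndarray
    sample_rate: float  # Hz
    t0: float = 0.0  # s
    units: str = "mbar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def __len__(self) -> int:
        return self.values.size

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Values with ``t_start <= t < t_end``; errors on an empty window."""
        mask = (self.t >= t_start) & (self.t < t_end)
        if not mask.any():
            raise ValueError(f"window [{t_start}, {t_end}) contains no samples")
        return self.values[mask]


@dataclass
class LungState:
    """Instantaneous state of the lung compartment."""

    volume_above_frc: float = 0.0  # ml
    alveolar_pressure: float = 0.0  # mbar
    airway_pressure: float = 0.0  # mbar, at the proximal sensor
    flow: float = 0.0  # ml/s, positive into the lung


def generate_compression_waveform(
    profile: CompressionProfile, duration: float, sample_rate: float
) -> PressureSeries:
    """Pleural-pressure waveform of periodic chest compressions.

    Each cycle of length ``60/rate`` s rises to ``pleural_amplitude`` during
    the compression phase and returns to 0 during decompression; zero before
    ``start_time``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 2.0 * profile.rate / 60.0:
        raise ValueError("sample_rate must resolve the compression frequency")
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    period = profile.period
    comp = profile.duty_fraction * period
    phase = np.mod(t - profile.start_time, period)
    amp = profile.pleural_amplitude
    values = np.zeros_like(t)
    if profile.waveform_shape == "half_sine":
        in_comp = phase < comp
        values[in_comp] = amp * np.sin(np.pi * phase[in_comp] / comp)
    else:  # trapezoid
        rise = min(profile.rise_time, comp / 2.0)
        if rise > 0:
            up = phase < rise
            values[up] = amp * phase[up] / rise
            down = (phase >= comp - rise) & (phase < comp)
            values[down] = amp * (comp - phase[down]) / rise
            flat = (phase >= rise) & (phase < comp - rise)
            values[flat] = amp
        else:
            values[phase < comp] = amp
    values[t < profile.start_time] = 0.0
    return PressureSeries(values, sample_rate, units="mbar")


def step_lung(
    state: LungState,
    params: LungParams,
    *,
    airway_pressure: Optional[float] = None,
    flow: Optional[float] = None,
    pleural_pressure: float = 0.0,
    dt: float,
    extra_resistance: float = 0.0,
) -> LungState:
    """Advance the one-compartment lung by ``dt`` seconds.

    Exactly one of ``airway_pressure`` (pressure at the driving source, mbar)
    or ``flow`` (commanded flow into the lung, ml/s) must be given.

    Pressure-driven: the linear ODE is integrated exactly over the step with
    the inputs held constant; ``extra_resistance`` (e.g. the expiratory valve)
    adds in series with the airway resistance, and the reported
    ``airway_pressure`` is the pressure at the proximal sensor between the two
    resistances.  Flow-driven: the volume is advanced by ``flow * dt`` and the
    sensor sees ``P_alv + R * flow``.

    The reported ``flow`` is the mean flow over the step, so cumulative
    ``flow * dt`` reproduces the volume trace identically.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (airway_pressure is None) == (flow is None):
        raise ValueError("supply exactly one of airway_pressure or flow")

    C, R = params.compliance, params.resistance
    v = state.volume_above_frc

    if flow is not None:
        v_new = max(v + flow * dt, -params.frc)
        mean_flow = (v_new - v) / dt
        p_alv = v_new / C + pleural_pressure
        p_sens = p_alv + R * mean_flow
    else:
        r_tot = R + extra_resistance
        v_eq = C * (airway_pressure - pleural_pressure)
        v_new = v_eq + (v - v_eq) * math.exp(-dt / (r_tot * C))
        v_new = max(v_new, -params.frc)
        mean_flow = (v_new - v) / dt
        p_alv = v_new / C + pleural_pressure
        inst_flow = (airway_pressure - p_alv) / r_tot
        p_sens = airway_pressure - inst_flow * extra_resistance
    return LungState(
        volume_above_frc=v_new,
        alveolar_pressure=p_alv,
        airway_pressure=p_sens,
        flow=mean_flow,
    )


@dataclass(frozen=True)
class Event:
    """Timestamped simulation event."""

    time: float  # s
    kind: Literal[
        "compression_onset", "trigger", "inspiration_start", "inspiration_end"
    ]


@dataclass
class SimulationResult:
    """Bundle of synchronized traces and the controller event log."""

    time: np.ndarray  # s, at the output sample rate
    airway: PressureSeries  # mbar, proximal sensor
    pleural: PressureSeries  # mbar
    flow: PressureSeries  # ml/s
    volume: PressureSeries  # ml above FRC
    events: list[Event]
    sample_rate: float
    mode: str

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.kind == kind])


def simulate(
    compression: CompressionProfile,
    lung: LungParams,
    ventilator: IPPVSettings | CCSVPreset | None,
    duration: float,
    sample_rate: float = 100.0,
    trigger: TriggerConfig | None = None,
    seed: int | None = None,
    sensor_noise_sd: float = 0.0,
    dt: float = 0.001,
) -> SimulationResult:
    """Closed-loop simulation of ventilator + compressions acting on the lung.

    ``ventilator`` selects the mode: :class:`IPPVSettings` runs volume-
    controlled IPPV, :class:`CCSVPreset` (with an optional
    :class:`TriggerConfig`) runs CCSV, ``None`` leaves the airway open to
    atmosphere (e.g. the untreated-arrest interval).  Integration runs on the
    internal ``dt`` grid (default 1 ms) and output is decimated to
    ``sample_rate`` (default 100 Hz).  ``sensor_noise_sd`` adds Gaussian noise
    (mbar) to the proximal pressure signal the controller reads; ``seed``
    makes it reproducible.

    Returns all traces on a common time base plus an event log holding every
    compression onset, trigger, and inspiration start/end.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    decim = 1.0 / (dt * sample_rate)
    if abs(decim - round(decim)) > 1e-9 or round(decim) < 1:
        raise ValueError("sample_rate must divide the internal rate 1/dt")
    decim = int(round(decim))

    if isinstance(ventilator, IPPVSettings):
        controller = IPPVController(ventilator)
    elif isinstance(ventilator, CCSVPreset):
        controller = CCSVController(ventilator, trigger)
    elif ventilator is None:
        controller = None
    else:
        raise TypeError(f"unsupported ventilator settings {type(ventilator).__name__}")

    n = int(round(duration / dt))
    ppl = generate_compression_waveform(compression, duration, 1.0 / dt).values
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, sensor_noise_sd, n) if sensor_noise_sd > 0 else np.zeros(n)
    )

    paw_out = np.empty(n)
    flow_out = np.empty(n)
    vol_out = np.empty(n)
    events: list[Event] = [
        Event(t, "compression_onset") for t in compression.onsets(duration)
    ]

    peep = getattr(ventilator, "peep", 0.0) if ventilator is not None else 0.0
    limit = ventilator.pressure_limit if isinstance(ventilator, IPPVSettings) else None
    state = LungState()
    sensed = 0.0  # controller's view of paw at the previous step
    C, R = lung.compliance, lung.resistance

    for i in range(n):
        t = i * dt
        p_pl = ppl[i]
        if controller is None:
            cmd = {"drive": "pressure", "paw": 0.0, "flow": 0.0}
        else:
            cmd = controller.step(sensed, dt)
            if cmd.get("inspiration_started"):
                events.append(Event(t, "inspiration_start"))
                if cmd.get("triggered"):
                    events.append(Event(t, "trigger"))
            if cmd.get("inspiration_ended"):
                # the transition step itself is still inspiratory
                events.append(Event(t + dt, "inspiration_end"))

        inspiratory = (
            cmd["flow"] > 0.0
            or cmd["paw"] > peep
            or (
                cmd["drive"] == "flow"
                and controller is not None
                and controller.state.phase == "inspiration"
            )
        )
        if cmd["drive"] == "flow" and inspiratory:
            q = cmd["flow"]
            if limit is not None:
                # hard machine limit: cap flow so sensor paw cannot exceed it
                q_max = (limit - state.volume_above_frc / C - p_pl) / (R + dt / C)
                q = min(q, max(q_max, 0.0))
            state = step_lung(
                state, lung, flow=q, pleural_pressure=p_pl, dt=dt
            )
        elif cmd["drive"] == "pressure" and inspiratory:
            state = step_lung(
                state, lung, airway_pressure=cmd["paw"], pleural_pressure=p_pl, dt=dt
            )
        else:
            # expiration / no ventilator: open to PEEP through the expiratory valve
            state = step_lung(
                state,
                lung,
                airway_pressure=peep,
                pleural_pressure=p_pl,
                dt=dt,
                extra_resistance=lung.valve_resistance,
            )

        sensed = state.airway_pressure + noise[i]
        paw_out[i] = sensed
        flow_out[i] = state.flow
        vol_out[i] = state.volume_above_frc

    events.sort(key=lambda e: (e.time, e.kind))
    # Decimate: each output sample k covers the internal block
    # [k/fs, (k+1)/fs).  Pressures and volume are the instantaneous values at
    # the end of the block; flow is the block mean, so that
    # cumsum(flow)/sample_rate reproduces the volume trace exactly.
    n_out = n // decim
    end = slice(decim - 1, n_out * decim, decim)
    time = np.arange(n_out) / sample_rate
    flow_dec = flow_out[: n_out * decim].reshape(n_out, decim).mean(axis=1)
    mode = controller.mode if controller is not None else "none"
    return SimulationResult(
        time=time,
        airway=PressureSeries(paw_out[end], sample_rate, units="mbar"),
        pleural=PressureSeries(ppl[end], sample_rate, units="mbar"),
        flow=PressureSeries(flow_dec, sample_rate, units="ml/s"),
        volume=PressureSeries(vol_out[end], sample_rate, units="ml"),
        events=events,
        sample_rate=sample_rate,
        mode=mode,
    )
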