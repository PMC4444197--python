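"""Ventilator controllers: volume-controlled IPPV and the CCSV inverse-trigger mode.

Two controllers are implemented as pure step functions plus small stateful
wrappers:

* **IPPV** — intermittent positive pressure ventilation: constant inspiratory
  flow delivering a fixed tidal volume at a fixed rate, passive expiration to
  PEEP, with a flow-throttling upper airway-pressure limit.
* **CCSV** — chest compression synchronized ventilation: a pressure-controlled
  breath started by an *inverse trigger* that detects the airway-pressure rise
  produced by a chest compression (level + gradient + minimum-expiration
  criteria) and cycled off after a fixed, short inspiratory time.

Pressures are in mbar, times in seconds unless a field name says ``_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "IPPVSettings",
    "TriggerConfig",
    "CCSVPreset",
    "ControllerState",
    "BreathSchedule",
    "ippv_schedule",
    "ippv_command",
    "ccsv_trigger_check",
    "ccsv_command",
    "IPPVController",
    "CCSVController",
    "STANDARD_PRESETS",
]

# Fixed cycling-time window of the CCSV mode, ms.
CCSV_T_INSP_RANGE = (205.0, 340.0)
# User-adjustable inverse-trigger ranges.
TRIGGER_LEVEL_RANGE = (0.9, 3.7)  # mbar above PEEP
TRIGGER_GRADIENT_RANGE = (25.0, 375.0)  # mbar/s
TRIGGER_MIN_EXP_RANGE = (200.0, 340.0)  # ms


class IPPVSettings(BaseModel):
    """Volume-controlled IPPV settings.

    Defaults follow guideline-style resuscitation ventilation: 7 ml/kg tidal
    volume at 10 breaths/min, I:E 1:1.5, no PEEP, pure oxygen, and an upper
    airway-pressure limit of 60 mbar.
    """

    model_config = ConfigDict(extra="forbid")

    tidal_volume_per_kg: float = 7.0  # ml/kg
    respiratory_rate: float = 10.0  # breaths/min
    ie_ratio: Tuple[float, float] = (1.0, 1.5)
    peep: float = 0.0  # mbar
    fio2: float = 1.0
    pressure_limit: float = 60.0  # mbar
    body_mass: float = 51.75  # kg

    @model_validator(mode="after")
    def _check(self) -> "IPPVSettings":
        if self.tidal_volume_per_kg <= 0:
            raise ValueError("tidal_volume_per_kg must be positive")
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate must be positive")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        i, e = self.ie_ratio
        if i <= 0 or e <= 0:
            raise ValueError("ie_ratio components must be positive")
        if not 0.0 <= self.fio2 <= 1.0:
            raise ValueError("fio2 must lie in [0, 1]")
        if self.pressure_limit <= self.peep:
            raise ValueError("pressure_limit must exceed peep")
        return self


class TriggerConfig(BaseModel):
    """Inverse-trigger parameters of the CCSV mode.

    The trigger fires when, simultaneously, airway pressure exceeds
    ``peep + level_above_peep``, the pressure gradient is at least
    ``gradient_threshold``, and at least ``min_expiration`` ms of expiration
    have elapsed.  Each parameter is restricted to the device's adjustable
    range; the defaults sit mid-range.
    """

    model_config = ConfigDict(extra="forbid")

    level_above_peep: float = 1.5  # mbar
    gradient_threshold: float = 100.0  # mbar/s
    min_expiration: float = 210.0  # ms

    @model_validator(mode="after")
    def _check(self) -> "TriggerConfig":
        for value, (lo, hi), name in (
            (self.level_above_peep, TRIGGER_LEVEL_RANGE, "level_above_peep"),
            (self.gradient_threshold, TRIGGER_GRADIENT_RANGE, "gradient_threshold"),
            (self.min_expiration, TRIGGER_MIN_EXP_RANGE, "min_expiration"),
        ):
            if not lo <= value <= hi:
                raise ValueError(
                    f"{name}={value} outside allowed range [{lo}, {hi}]"
                )
        return self


#: The three study presets: (P_insp mbar, T_insp ms).
STANDARD_PRESETS = {
    "A": (60.0, 205.0),
    "B": (60.0, 265.0),
    "C": (45.0, 265.0),
}


class CCSVPreset(BaseModel):
    """Pressure preset of a CCSV breath: plateau pressure and fixed inspiratory time.

    ``CCSVPreset.named("A"|"B"|"C")`` builds the standard presets
    A = (60 mbar, 205 ms), B = (60 mbar, 265 ms), C = (45 mbar, 265 ms).
    A preset constructed with an explicit ``name`` must match the standard
    table; leave ``name=None`` for custom settings.
    """

    model_config = ConfigDict(extra="forbid")

    name: Optional[Literal["A", "B", "C"]] = None
    p_insp: float = 60.0  # mbar
    t_insp: float = 205.0  # ms
    peep: float = 0.0  # mbar
    fio2: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "CCSVPreset":
        lo, hi = CCSV_T_INSP_RANGE
        if not lo <= self.t_insp <= hi:
            raise ValueError(f"t_insp={self.t_insp} ms outside allowed range [{lo}, {hi}]")
        if self.p_insp <= self.peep:
            raise ValueError("p_insp must exceed peep")
        if self.name is not None:
            p, t = STANDARD_PRESETS[self.name]
            if (self.p_insp, self.t_insp) != (p, t):
                raise ValueError(
                    f"preset {self.name} is fixed at p_insp={p} mbar, t_insp={t} ms"
                )
        return self

    @classmethod
    def named(cls, name: str) -> "CCSVPreset":
        try:
            p_insp, t_insp = STANDARD_PRESETS[name.upper()]
        except KeyError:
            raise ValueError(f"unknown CCSV preset {name!r}; expected A, B or C") from None
        return cls(name=name.upper(), p_insp=p_insp, t_insp=t_insp)


@dataclass
class ControllerState:
    """Breath-phase bookkeeping shared by both controllers."""

    phase: Literal["inspiration", "expiration"] = "expiration"
    phase_elapsed: float = float("inf")  # ms; starts mid-expiration
    breaths_delivered: int = 0


@dataclass(frozen=True)
class BreathSchedule:
    """Derived IPPV cycle quantities."""

    t_insp: float  # s
    t_exp: float  # s
    tidal_volume: float  # ml
    constant_flow: float  # ml/s


def ippv_schedule(settings: IPPVSettings) -> BreathSchedule:
    """Derive the IPPV cycle timing and flow from the settings.

    The cycle length is ``60/rate`` split by the I:E ratio; the constant
    inspiratory flow is the tidal volume divided by the inspiratory time.
    At 10/min with I:E 1:1.5 this gives 2.4 s inspiration and 3.6 s expiration.
    """
    cycle = 60.0 / settings.respiratory_rate
    i, e = settings.ie_ratio
    t_insp = cycle * i / (i + e)
    t_exp = cycle - t_insp
    tidal_volume = settings.tidal_volume_per_kg * settings.body_mass
    return BreathSchedule(
        t_insp=t_insp,
        t_exp=t_exp,
        tidal_volume=tidal_volume,
        constant_flow=tidal_volume / t_insp,
    )


# Pressure margin (mbar) over which the IPPV limit valve throttles flow
# proportionally; keeps delivered paw at or below the limit without a hard
# on/off chatter.
_LIMIT_MARGIN = 2.0


def ippv_command(
    state: ControllerState,
    schedule: BreathSchedule,
    measured_paw: float,
    dt: float,
    pressure_limit: float = 60.0,
) -> Tuple[float, ControllerState]:
    """One IPPV controller step: commanded flow (ml/s) and the advanced state.

    Constant flow during inspiration, zero commanded flow during expiration
    (exhalation is passive through the expiratory valve).  As measured airway
    pressure approaches ``pressure_limit`` the flow is throttled proportionally
    so the limit is not exceeded; the breath is never cycled off early.
    """
    new = ControllerState(state.phase, state.phase_elapsed, state.breaths_delivered)
    if new.phase == "inspiration":
        flow = schedule.constant_flow
        if measured_paw >= pressure_limit:
            flow = 0.0
        elif measured_paw > pressure_limit - _LIMIT_MARGIN:
            flow *= (pressure_limit - measured_paw) / _LIMIT_MARGIN
    else:
        flow = 0.0

    new.phase_elapsed += dt * 1000.0
    if new.phase == "inspiration" and new.phase_elapsed >= schedule.t_insp * 1000.0:
        new.phase = "expiration"
        new.phase_elapsed = 0.0
    elif new.phase == "expiration" and new.phase_elapsed >= schedule.t_exp * 1000.0:
        new.phase = "inspiration"
        new.phase_elapsed = 0.0
        new.breaths_delivered += 1
    return flow, new


def ccsv_trigger_check(
    paw_prev: float,
    paw_now: float,
    sample_spacing: float,
    peep: float,
    expiration_elapsed: float,
    config: TriggerConfig,
) -> bool:
    """Inverse-trigger decision from the last two airway-pressure samples.

    Returns True iff all three criteria hold at once:

    1. ``paw_now > peep + level_above_peep`` — pressure is above the level;
    2. ``(paw_now - paw_prev)/sample_spacing >= gradient_threshold`` —
       pressure is rising fast enough;
    3. ``expiration_elapsed >= min_expiration`` — enough expiration
       (chest decompression) has occurred.

    Pure function of its inputs.  ``sample_spacing`` is in seconds,
    ``expiration_elapsed`` in ms.
    """
    if sample_spacing <= 0:
        raise ValueError("sample_spacing must be positive")
    if expiration_elapsed < 0:
        raise ValueError("expiration_elapsed must be non-negative")
    level_ok = paw_now > peep + config.level_above_peep
    gradient_ok = (paw_now - paw_prev) / sample_spacing >= config.gradient_threshold
    expiration_ok = expiration_elapsed >= config.min_expiration
    return level_ok and gradient_ok and expiration_ok


def ccsv_command(
    state: ControllerState,
    preset: CCSVPreset,
    trigger_fired: bool,
    dt: float,
) -> Tuple[float, ControllerState]:
    """One CCSV controller step: commanded airway pressure (mbar) and new state.

    A trigger during expiration starts an inspiration commanding
    ``p_insp``; after exactly ``t_insp`` ms the breath cycles off and the
    command returns to PEEP.  Triggers arriving during inspiration are
    ignored (fixed-time cycling, no retriggering).
    """
    new = ControllerState(state.phase, state.phase_elapsed, state.breaths_delivered)
    if new.phase == "expiration" and trigger_fired:
        new.phase = "inspiration"
        new.phase_elapsed = 0.0
        new.breaths_delivered += 1

    commanded = preset.p_insp if new.phase == "inspiration" else preset.peep

    new.phase_elapsed += dt * 1000.0
    if new.phase == "inspiration" and new.phase_elapsed >= preset.t_insp:
        new.phase = "expiration"
        new.phase_elapsed = 0.0
    return commanded, new


class IPPVController:
    """Stateful wrapper driving :func:`ippv_command` on a fixed time grid."""

    mode = "IPPV"

    def __init__(self, settings: IPPVSettings):
        self.settings = settings
        self.schedule = ippv_schedule(settings)
        # Start at the onset of the first inspiration.
        self.state = ControllerState(phase="inspiration", phase_elapsed=0.0)

    def step(self, paw_now: float, dt: float) -> dict:
        starting = (
            self.state.phase == "inspiration" and self.state.phase_elapsed == 0.0
        )
        flow, self.state = ippv_command(
            self.state, self.schedule, paw_now, dt, self.settings.pressure_limit
        )
        return {
            "drive": "flow",
            "flow": flow,
            "paw": self.settings.peep,
            "inspiration_started": starting,
            "inspiration_ended": self.state.phase == "expiration"
            and self.state.phase_elapsed == 0.0,
            "triggered": False,
        }


class CCSVController:
    """Stateful wrapper combining the inverse trigger with fixed-time cycling.

    The pressure gradient is estimated by a backward difference over
    ``grad_window_ms`` (default 5 ms) of the controller's own sample history,
    which smooths single-sample noise on the 1 ms internal grid.
    """

    mode = "CCSV"

    def __init__(
        self,
        preset: CCSVPreset,
        trigger: TriggerConfig | None = None,
        grad_window_ms: float = 5.0,
    ):
        self.preset = preset
        self.trigger = trigger or TriggerConfig()
        self.grad_window_ms = grad_window_ms
        self.state = ControllerState()
        self._history: list[float] = []

    def step(self, paw_now: float, dt: float) -> dict:
        lag = max(1, round(self.grad_window_ms / 1000.0 / dt))
        if self._history:
            k = min(lag, len(self._history))
            paw_prev = self._history[-k]
            spacing = k * dt
        else:  # first sample: no gradient information yet
            paw_prev, spacing = paw_now, dt
        self._history.append(paw_now)
        if len(self._history) > lag + 1:
            del self._history[0]

        fired = False
        if self.state.phase == "expiration":
            fired = ccsv_trigger_check(
                paw_prev,
                paw_now,
                spacing,
                self.preset.peep,
                self.state.phase_elapsed,
                self.trigger,
            )
        before = self.state.breaths_delivered
        commanded, self.state = ccsv_command(self.state, self.preset, fired, dt)
        started = self.state.breaths_delivered > before
        return {
            "drive": "pressure",
            "flow": 0.0,
            "paw": commanded,
            "inspiration_started": started,
            "inspiration_ended": self.state.phase == "expiration"
            and self.state.phase_elapsed == 0.0
            and not started,
            "triggered": started,
        }
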