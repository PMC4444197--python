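"""Breath/compression event extraction and synchronization & pressure metrics.

Works on simulated runs (where the controller event log gives exact breath
boundaries) or on recorded traces (threshold-based onset detection).  Also
houses the hemodynamic window aggregates (MAP, CVP, MAP−CVP) and pressure
unit conversion between mmHg, kPa and mbar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .cpr_mechanics import Event, PressureSeries, SimulationResult

__all__ = [
    "BreathEvent",
    "PeriodSummary",
    "SyncMetrics",
    "detect_breaths",
    "sync_metrics",
    "period_pressure_aggregates",
    "convert_pressure",
]


@dataclass(frozen=True)
class BreathEvent:
    """One detected insufflation."""

    t_start: float  # s
    t_end: float  # s
    mode: str  # "IPPV" | "CCSV"
    peak_paw: float  # mbar
    tidal_volume: float  # ml, integral of inspiratory flow
    matched_compression_index: Optional[int] = None
    trigger_latency: Optional[float] = None  # ms after compression onset

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.tidal_volume < 0:
            raise ValueError("tidal_volume must be non-negative")


@dataclass
class PeriodSummary:
    """Per-period report row of ventilation and hemodynamic aggregates."""

    period: str
    breaths: int
    breath_rate: float  # /min
    median_peak_paw: float  # mbar
    minute_ventilation: float  # ml/min
    sync_fraction: float
    map: Optional[float] = None  # mmHg
    cvp: Optional[float] = None  # mmHg
    map_minus_cvp: Optional[float] = None  # mmHg


def _integrate_inspired(
    flow: PressureSeries, t_start: float, t_end: float
) -> float:
    """Integral of positive flow over the event, ml.

    The window is widened by one sample period on each side so that boundary
    samples straddling the onset/cycle-off are counted; clipping at zero
    keeps expiratory flow out.
    """
    t = flow.t
    pad = 1.0 / flow.sample_rate
    mask = (t >= t_start - pad) & (t < t_end + pad)
    return float(np.clip(flow.values[mask], 0.0, None).sum() / flow.sample_rate)


def detect_breaths(
    paw: PressureSeries,
    flow: PressureSeries,
    mode: str,
    events: Sequence[Event] | None = None,
    onset_threshold: float = 1.0,
    sustain_ms: float = 30.0,
    peep: float = 0.0,
) -> list[BreathEvent]:
    """Extract breath events from an airway-pressure + flow trace pair.

    If a controller ``events`` log is supplied (simulated data), the logged
    inspiration start/end pairs define the breath boundaries exactly.  On
    recorded traces, an inspiration starts where paw crosses
    ``peep + onset_threshold`` upward and stays above it for at least
    ``sustain_ms``, and ends where paw falls back below the threshold.  Per
    breath, tidal volume is the integral of positive flow over the event and
    ``peak_paw`` the maximum airway pressure.
    """
    if len(paw) != len(flow) or paw.sample_rate != flow.sample_rate:
        raise ValueError("paw and flow series must share a time base")
    duration = len(paw) / paw.sample_rate

    bounds: list[tuple[float, float]] = []
    if events is not None:
        start: float | None = None
        for e in sorted(events, key=lambda e: e.time):
            if e.kind == "inspiration_start":
                start = e.time
            elif e.kind == "inspiration_end" and start is not None:
                bounds.append((start, e.time))
                start = None
        if start is not None and duration > start:
            bounds.append((start, duration))
    else:
        thr = peep + onset_threshold
        above = paw.values > thr
        t = paw.t
        n_sustain = max(1, int(round(sustain_ms / 1000.0 * paw.sample_rate)))
        i = 0
        n = len(above)
        while i < n:
            if above[i] and (i == 0 or not above[i - 1]):
                j = i
                while j < n and above[j]:
                    j += 1
                if j - i >= n_sustain:
                    bounds.append((t[i], t[j - 1] + 1.0 / paw.sample_rate))
                i = j
            else:
                i += 1

    breaths = []
    for t0, t1 in bounds:
        win = (paw.t >= t0) & (paw.t < t1)
        peak = float(paw.values[win].max()) if win.any() else float("nan")
        breaths.append(
            BreathEvent(
                t_start=t0,
                t_end=t1,
                mode=mode,
                peak_paw=peak,
                tidal_volume=_integrate_inspired(flow, t0, t1),
            )
        )
    return breaths


@dataclass
class SyncMetrics:
    """Breath-to-compression synchronization summary."""

    sync_fraction: float  # matched breaths / compressions
    n_breaths: int
    n_compressions: int
    latency_median: Optional[float]  # ms
    latency_q25: Optional[float]
    latency_q75: Optional[float]


def sync_metrics(
    breaths: Sequence[BreathEvent],
    compression_onsets: Iterable[float],
    compression_period: float | None = None,
) -> SyncMetrics:
    """Match each breath to the nearest preceding compression onset.

    A breath counts as synchronized when its start falls within one
    compression period after an onset; each compression can match at most one
    breath.  ``sync_fraction`` is matched breaths over compressions; the
    latency statistics (ms from onset to inspiration start) summarize the
    matched pairs.
    """
    onsets = np.sort(np.asarray(list(compression_onsets), dtype=float))
    starts = np.array([b.t_start for b in breaths])
    if onsets.size == 0:
        if starts.size:
            warnings.warn("no compressions to match breaths against")
        return SyncMetrics(0.0, len(breaths), 0, None, None, None)
    if compression_period is None:
        compression_period = (
            float(np.median(np.diff(onsets))) if onsets.size > 1 else np.inf
        )

    latencies = []
    used: set[int] = set()
    for s in np.sort(starts):
        k = int(np.searchsorted(onsets, s, side="right")) - 1
        if k < 0 or k in used:
            continue
        lag = s - onsets[k]
        if lag < compression_period:
            used.add(k)
            latencies.append(lag * 1000.0)
    frac = len(used) / onsets.size
    lat = np.array(latencies)
    return SyncMetrics(
        sync_fraction=frac,
        n_breaths=len(breaths),
        n_compressions=int(onsets.size),
        latency_median=float(np.median(lat)) if lat.size else None,
        latency_q25=float(np.percentile(lat, 25)) if lat.size else None,
        latency_q75=float(np.percentile(lat, 75)) if lat.size else None,
    )


def period_pressure_aggregates(
    arterial: PressureSeries,
    venous: PressureSeries,
    window: tuple[float, float],
) -> dict:
    """Time-averaged MAP, CVP and MAP−CVP (mmHg) over ``window`` seconds."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    map_ = float(arterial.window(t0, t1).mean())
    cvp = float(venous.window(t0, t1).mean())
    return {"map": map_, "cvp": cvp, "map_minus_cvp": map_ - cvp}


# exact linear conversion factors to kPa
_TO_KPA = {"kPa": 1.0, "mmHg": 0.1333224, "mbar": 0.1}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg, kPa and mbar (exact linear factors)."""
    try:
        f_in, f_out = _TO_KPA[from_unit], _TO_KPA[to_unit]
    except KeyError as err:
        raise ValueError(
            f"unknown pressure unit {err.args[0]!r}; expected one of {sorted(_TO_KPA)}"
        ) from None
    return value * f_in / f_out


def summarize_period(
    result: SimulationResult,
    period: str,
    arterial: PressureSeries | None = None,
    venous: PressureSeries | None = None,
) -> PeriodSummary:
    """Build the per-period report row from a simulation segment."""
    breaths = detect_breaths(result.airway, result.flow, result.mode, result.events)
    duration_min = len(result.airway) / result.sample_rate / 60.0
    sync = sync_metrics(breaths, result.event_times("compression_onset"))
    hemo = (
        period_pressure_aggregates(
            arterial, venous, (0.0, len(arterial) / arterial.sample_rate)
        )
        if arterial is not None and venous is not None
        else {"map": None, "cvp": None, "map_minus_cvp": None}
    )
    return PeriodSummary(
        period=period,
        breaths=len(breaths),
        breath_rate=len(breaths) / duration_min if duration_min else 0.0,
        median_peak_paw=float(np.median([b.peak_paw for b in breaths]))
        if breaths
        else 0.0,
        minute_ventilation=sum(b.tidal_volume for b in breaths) / duration_min
        if duration_min
        else 0.0,
        sync_fraction=sync.sync_fraction,
        **hemo,
    )
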