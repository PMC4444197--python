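"""Cross-over protocol: allocation orders, randomization, five-period timeline.

The study design fixes IPPV as the first and fifth ventilation period of every
subject and permutes the three CCSV presets over periods 2–4, giving 3! = 6
possible allocation orders; a balanced randomization assigns each order
equally often, which requires the number of subjects to be a multiple of 6.
The timeline is 3 min of untreated ventricular fibrillation followed by five
4-min ventilation periods under continuous chest compressions, with blood-gas
sampling instants carried as metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import breath_metrics
from .cpr_mechanics import CompressionProfile, LungParams, SimulationResult, simulate
from .ventilator_modes import CCSVPreset, IPPVSettings, TriggerConfig

__all__ = [
    "AllocationOrder",
    "ProtocolTimeline",
    "ProtocolResult",
    "enumerate_orders",
    "randomize_allocation",
    "run_protocol",
]

PERIOD_LABELS = ("IPPV_first", "CCSV_A", "CCSV_B", "CCSV_C", "IPPV_last")


@dataclass(frozen=True)
class AllocationOrder:
    """Sequence of the five period treatments for one subject."""

    periods: tuple[str, str, str, str, str]

    def __post_init__(self) -> None:
        if self.periods[0] != "IPPV_first" or self.periods[-1] != "IPPV_last":
            raise ValueError("first and last periods must be IPPV")
        if sorted(self.periods[1:4]) != ["CCSV_A", "CCSV_B", "CCSV_C"]:
            raise ValueError("middle periods must be a permutation of the CCSV presets")

    def __iter__(self):
        return iter(self.periods)


@dataclass(frozen=True)
class ProtocolTimeline:
    """Fixed experiment timeline, minutes from VF induction."""

    vf_onset: float = 0.0
    cpr_start: float = 3.0
    period_length: float = 4.0
    n_periods: int = 5
    sampling_times: tuple[float, ...] = (0.0, 7.0, 11.0, 15.0, 19.0, 23.0)

    def period_boundaries(self) -> list[tuple[float, float]]:
        """(start, end) of each ventilation period, minutes."""
        return [
            (
                self.cpr_start + i * self.period_length,
                self.cpr_start + (i + 1) * self.period_length,
            )
            for i in range(self.n_periods)
        ]


def enumerate_orders() -> list[AllocationOrder]:
    """All six allocation orders, in lexicographic order of the CCSV block."""
    return [
        AllocationOrder(("IPPV_first", *middle, "IPPV_last"))
        for middle in itertools.permutations(("CCSV_A", "CCSV_B", "CCSV_C"))
    ]


def randomize_allocation(n_subjects: int, seed: int | None = None) -> list[AllocationOrder]:
    """Balanced randomized allocation: each order used exactly n/6 times.

    Requires ``n_subjects`` to be a multiple of 6 so that every CCSV preset
    appears equally often in every period position; the sequence is shuffled
    reproducibly by ``seed``.
    """
    if n_subjects <= 0 or n_subjects % 6 != 0:
        raise ValueError("n_subjects must be a positive multiple of 6")
    orders = enumerate_orders() * (n_subjects // 6)
    rng = np.random.default_rng(seed)
    return [orders[i] for i in rng.permutation(len(orders))]


@dataclass
class ProtocolResult:
    """Simulated five-period run for one subject."""

    order: AllocationOrder
    segments: dict[str, SimulationResult]
    summaries: dict[str, breath_metrics.PeriodSummary]
    timeline: ProtocolTimeline = field(default_factory=ProtocolTimeline)


def _ventilator_for(label: str, ippv: IPPVSettings) -> IPPVSettings | CCSVPreset:
    if label.startswith("IPPV"):
        return ippv
    return CCSVPreset.named(label.split("_")[-1])


def run_protocol(
    order: AllocationOrder,
    compression: CompressionProfile | None = None,
    lung: LungParams | None = None,
    ippv: IPPVSettings | None = None,
    trigger: TriggerConfig | None = None,
    period_duration: float = 240.0,
    sample_rate: float = 100.0,
    seed: int | None = None,
) -> ProtocolResult:
    """Simulate the five ventilation periods of one subject in ``order``.

    Each period runs the matching ventilator mode for ``period_duration``
    seconds under continuous compressions (lung state resets between periods;
    carry-over of mechanics across the mode switch is not modelled).  The
    preceding untreated-VF interval has no ventilation and no compressions and
    is represented only in the timeline metadata.
    """
    if not isinstance(order, AllocationOrder):
        order = AllocationOrder(tuple(order))
    compression = compression or CompressionProfile()
    lung = lung or LungParams()
    ippv = ippv or IPPVSettings()
    if period_duration <= 0:
        raise ValueError("period_duration must be positive")

    segments: dict[str, SimulationResult] = {}
    summaries: dict[str, breath_metrics.PeriodSummary] = {}
    for label in order:
        res = simulate(
            compression,
            lung,
            _ventilator_for(label, ippv),
            duration=period_duration,
            sample_rate=sample_rate,
            trigger=trigger,
            seed=seed,
        )
        segments[label] = res
        summaries[label] = breath_metrics.summarize_period(res, label)
    return ProtocolResult(order=order, segments=segments, summaries=summaries)
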