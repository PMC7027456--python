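"""Batch scheduling: stagger, concurrent growth batches, plant inventory.

The upstream plant-growth recipe is the facility bottleneck: batches are
started at a uniform stagger, each occupying growth space for the upstream
cycle time, with downstream processing slotted into the stagger window.  For
an indoor facility the stagger is the operating year divided by the batch
count; for a seasonal (outdoor) campaign the batch starts are packed into
the part of the growing season that still lets the last batch finish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ScheduleConfig
from .exceptions import SchedulingError


@dataclass
class ScheduleInputs:
    operating_days_per_year: float
    upstream_cycle_days: float
    downstream_cycle_days: float
    batch_duration_days: float
    batches_per_year: int
    seasonal: bool = False

    @classmethod
    def from_config(cls, cfg: ScheduleConfig) -> "ScheduleInputs":
        return cls(
            operating_days_per_year=cfg.operating_days_per_year,
            upstream_cycle_days=cfg.upstream_cycle_days,
            downstream_cycle_days=cfg.downstream_cycle_days,
            batch_duration_days=cfg.batch_duration_days,
            batches_per_year=cfg.batches_per_year,
            seasonal=cfg.seasonal,
        )


@dataclass
class ScheduleResult:
    batches_per_year: int
    stagger_days: float
    concurrent_growth_batches: int
    plant_inventory: int
    downstream_utilization: float

    def to_dict(self) -> dict:
        return {
            "batches_per_year": self.batches_per_year,
            "stagger_days": self.stagger_days,
            "concurrent_growth_batches": self.concurrent_growth_batches,
            "plant_inventory": self.plant_inventory,
            "downstream_utilization": self.downstream_utilization,
        }


def make_schedule(inputs: ScheduleInputs, plants_per_batch: int) -> ScheduleResult:
    """Compute the steady-state schedule for one scenario.

    Raises :class:`SchedulingError` naming the bottleneck if the downstream
    recipe cannot complete within the stagger between harvests.
    """
    n = inputs.batches_per_year
    if inputs.seasonal:
        # Outdoor campaign: all starts must fall early enough in the season
        # window for the last batch to reach harvest before the season ends.
        starts_window = inputs.operating_days_per_year - inputs.upstream_cycle_days
        if starts_window <= 0:
            raise SchedulingError(
                "upstream growth cycle "
                f"({inputs.upstream_cycle_days} d) does not fit in the "
                f"{inputs.operating_days_per_year} d seasonal window"
            )
        stagger = starts_window / max(n - 1, 1)
    else:
        stagger = inputs.operating_days_per_year / n
    if inputs.downstream_cycle_days > stagger:
        raise SchedulingError(
            "downstream processing is the bottleneck: recipe cycle "
            f"{inputs.downstream_cycle_days} d exceeds the {stagger:.3g} d "
            "stagger between harvests"
        )
    concurrent = min(math.ceil(inputs.upstream_cycle_days / stagger), n)
    return ScheduleResult(
        batches_per_year=n,
        stagger_days=stagger,
        concurrent_growth_batches=concurrent,
        plant_inventory=concurrent * plants_per_batch,
        downstream_utilization=inputs.downstream_cycle_days / stagger,
    )


def daily_occupancy(
    inputs: ScheduleInputs, resolution_per_day: int = 4
) -> np.ndarray:
    """Brute-force steady-state growth-space occupancy over one year.

    Simulates two consecutive years of uniformly staggered batch starts and
    counts, on a sub-daily grid over the second year, how many batches are
    simultaneously in their upstream growth cycle.  Used as the independent
    oracle for ``concurrent_growth_batches``.
    """
    result = make_schedule(inputs, plants_per_batch=1)
    stagger = result.stagger_days
    period = inputs.operating_days_per_year if not inputs.seasonal else 365.0
    starts = [
        year * period + i * stagger
        for year in (0, 1)
        for i in range(inputs.batches_per_year)
    ]
    times = np.arange(period, 2 * period, 1.0 / resolution_per_day)
    occupancy = np.zeros(times.shape, dtype=int)
    for start in starts:
        occupancy += (times >= start) & (times < start + inputs.upstream_cycle_days)
    return occupancy
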