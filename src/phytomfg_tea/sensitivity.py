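"""Sensitivity and scenario drivers.

Four kinds of analysis rebuild or rescale the facility around the base
design:

* purchase-price perturbation of single ledger items (tornado-style);
* expression-level scan at fixed demand (the facility is re-sized: biomass-
  and volume-driven costs scale as 1/E, product-mass-driven costs are held,
  and downstream AMP recovery is conservatively held fixed);
* annual-production scan at fixed expression level (variable costs scale
  linearly, labor and QC crews are held, equipment resizes along the
  power-law cost curve);
* named alternative-host scenarios, plus cost-of-use conversion of a COGS
  into $ per kg food or per L wash water at a stated application rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import ScenarioConfig
from .economics import CostReport
from .exceptions import ConfigurationError, EconomicsError
from .fixtures import emit_config
from .pipeline import ScenarioResult, run_pipeline

# Cost band of standard (non-biotic) food sanitizing treatments, $ per kg
# food, used as the comparator in cost-of-use reporting.
STANDARD_TREATMENT_BAND = (0.01, 0.10)


@dataclass
class ScanPoint:
    parameter_value: float
    cogs_per_g: float
    cogs_split: dict[str, float]
    aoc: float
    capex_total: float
    capex_by_section: dict[str, float]
    fw_per_batch_kg: float


@dataclass
class ScanResult:
    parameter: str
    points: list[ScanPoint]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    self.parameter: p.parameter_value,
                    "cogs_per_g": p.cogs_per_g,
                    "cogs_upstream_per_g": p.cogs_split.get("upstream", 0.0),
                    "cogs_downstream_per_g": p.cogs_split.get("downstream", 0.0),
                    "aoc": p.aoc,
                    "capex_total": p.capex_total,
                    "fw_per_batch_kg": p.fw_per_batch_kg,
                }
                for p in self.points
            ]
        )


@dataclass
class CostOfUseResult:
    juncture: str
    rate_low: float
    rate_high: float
    rate_unit: str
    cost_low: float
    cost_high: float
    cost_unit: str
    comparator_band: tuple[float, float] = STANDARD_TREATMENT_BAND

    def to_dict(self) -> dict:
        return {
            "juncture": self.juncture,
            "application_rate": [self.rate_low, self.rate_high],
            "rate_unit": self.rate_unit,
            "cost": [self.cost_low, self.cost_high],
            "cost_unit": self.cost_unit,
            "standard_treatment_band": list(self.comparator_band),
        }


def run_scenario(name: str) -> ScenarioResult:
    """Full pipeline on a named fixture scenario (base | spinach | tobacco)."""
    return run_pipeline(emit_config(name))


def price_sensitivity(
    config: ScenarioConfig, item_name: str, deltas: Sequence[float]
) -> dict[float, float]:
    """Percent change in COGS for each fractional price delta of one item.

    COGS is linear in any single unit price, so the response is exactly
    delta x (item cost / AOC) x 100; it is nevertheless computed by
    re-running the economics with the perturbed ledger.
    """
    base = run_pipeline(config)
    base.cost_report.item(item_name)  # raises with the ledger listing if absent
    out: dict[float, float] = {}
    for delta in deltas:
        perturbed = _with_item_price_scaled(config, item_name, 1.0 + delta)
        result = run_pipeline(perturbed)
        out[delta] = 100.0 * (
            result.cost_report.cogs_per_g / base.cost_report.cogs_per_g - 1.0
        )
    return out


def _with_item_price_scaled(
    config: ScenarioConfig, item_name: str, factor: float
) -> ScenarioConfig:
    new_ledger = []
    found = False
    for item in config.ledger:
        if item.name == item_name:
            found = True
            if item.kind == "computed":
                item = item.model_copy(update={"unit_price": item.unit_price * factor})
            else:
                item = item.model_copy(update={"annual_cost": item.annual_cost * factor})
        new_ledger.append(item)
    if not found:
        raise EconomicsError(
            f"no ledger item named {item_name!r}; ledger has: "
            + ", ".join(i.name for i in config.ledger)
        )
    return config.model_copy(update={"ledger": new_ledger})


def expression_scan(
    config: ScenarioConfig, expression_levels: Sequence[float]
) -> ScanResult:
    """Re-size the facility across expression levels (g AMP / kg FW).

    Downstream recovery is held fixed regardless of expression level;
    biomass- and volume-driven costs and equipment scale with the batch
    fresh weight (proportional to 1/E at fixed demand), product-mass-driven
    items are unchanged.
    """
    if any(e <= 0 for e in expression_levels):
        raise ConfigurationError("expression levels must be positive")
    if list(expression_levels) != sorted(set(expression_levels)):
        raise ConfigurationError("expression grid must be strictly increasing")
    base_e = config.host.expression_g_per_kg_fw
    points = []
    for e in expression_levels:
        scaled = config.model_copy(
            update={"host": config.host.model_copy(update={"expression_g_per_kg_fw": e})}
        )
        factor = base_e / e  # fresh-weight ratio relative to the reference design
        scale = {"biomass": factor, "volume": factor, "product": 1.0}
        result = run_pipeline(scaled, lump_scale=scale, size_scale=scale | {"product_mass": 1.0})
        points.append(_point(e, result))
    return ScanResult(parameter="expression_g_per_kg_fw", points=points)


def production_scan(config: ScenarioConfig, demands_kg: Sequence[float]) -> ScanResult:
    """Re-size the facility across annual production levels (kg AMP/yr).

    Materials and consumables scale with throughput; labor and QC crews are
    held; equipment capacity follows the six-tenths power law.
    """
    if any(d <= 0 for d in demands_kg):
        raise ConfigurationError("annual demands must be positive")
    if list(demands_kg) != sorted(set(demands_kg)):
        raise ConfigurationError("demand grid must be strictly increasing")
    base_demand = config.annual_demand_kg
    points = []
    for demand in demands_kg:
        scaled = config.model_copy(update={"annual_demand_kg": demand})
        factor = demand / base_demand
        scale = {"biomass": factor, "volume": factor, "product": factor}
        result = run_pipeline(scaled, lump_scale=scale, size_scale=scale | {"product_mass": factor})
        points.append(_point(demand, result))
    return ScanResult(parameter="annual_demand_kg", points=points)


def _point(value: float, result: ScenarioResult) -> ScanPoint:
    report = result.cost_report
    return ScanPoint(
        parameter_value=value,
        cogs_per_g=report.cogs_per_g,
        cogs_split=dict(report.cogs_split),
        aoc=report.aoc,
        capex_total=report.capex_total,
        capex_by_section=dict(report.capex_by_section),
        fw_per_batch_kg=result.plan.fw_per_batch_kg,
    )


_JUNCTURE_UNITS = {
    "animal_wash": ("mg AMP/L wash", "$/L wash"),
    "carcass_spray": ("mg AMP/L wash", "$/L wash"),
    "meat_product": ("mg AMP/kg meat", "$/kg meat"),
}


def cost_of_use(
    cogs_per_g: float, juncture: str, rate_range: tuple[float, float]
) -> CostOfUseResult:
    """Treatment cost band at an application rate range.

    Rates are in mg AMP per kg food (meat product) or per L wash water
    (animal wash, carcass spray); ppm in water is equivalent to mg/L.  Cost
    = rate x COGS / 1000.
    """
    if juncture not in _JUNCTURE_UNITS:
        raise ConfigurationError(
            f"unknown juncture {juncture!r}; expected one of {sorted(_JUNCTURE_UNITS)}"
        )
    low, high = rate_range
    if low < 0 or high < low:
        raise ConfigurationError(f"invalid application-rate range {rate_range}")
    rate_unit, cost_unit = _JUNCTURE_UNITS[juncture]
    return CostOfUseResult(
        juncture=juncture,
        rate_low=low,
        rate_high=high,
        rate_unit=rate_unit,
        cost_low=low * cogs_per_g / 1000.0,
        cost_high=high * cogs_per_g / 1000.0,
        cost_unit=cost_unit,
    )


def substrate_reuse_counterfactual(config: ScenarioConfig) -> dict[str, float]:
    """Annual-operating-cost effect of reusing the soilless substrate once.

    A single reuse halves the annual substrate consumable cost; the AOC
    reduction is computed through the full ledger, not assumed.
    """
    base = run_pipeline(config)
    reused = run_pipeline(
        _with_item_price_scaled(config, "soilless plant substrate", 0.5)
    )
    return {
        "aoc_base": base.cost_report.aoc,
        "aoc_with_reuse": reused.cost_report.aoc,
        "aoc_reduction_pct": 100.0
        * (1.0 - reused.cost_report.aoc / base.cost_report.aoc),
    }
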