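"""Full scenario pipeline: config -> upstream plan -> batch propagation ->
schedule -> resolved cost ledger -> cost report.

The ledger's "computed" lines are priced against physical quantities the
model itself produces (plants, seed grams, nutrient litres, buffer
kilograms), so a change anywhere upstream of the ledger (expression level,
recovery, batch count) propagates into the economics without any manual
re-calibration.  Facility re-design scans pass ``lump_scale`` multipliers
(per scaling rule) for the calibrated lump-sum lines and resize equipment
through the same rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .config import ScenarioConfig
from .downstream import (
    ProductQuality,
    overall_recovery_from_config,
    quality_metrics,
    run_downstream,
)
from .economics import (
    CostItem,
    CostReport,
    EquipmentItem,
    build_cost_report,
)
from .exceptions import ConfigurationError
from .flowsheet import StageRecord
from .scheduling import ScheduleInputs, ScheduleResult, make_schedule
from .upstream import UpstreamBatchPlan, size_batches

logger = logging.getLogger("phytomfg_tea")

_NO_SCALE: Mapping[str, float] = {}


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    plan: UpstreamBatchPlan
    stage_records: list[StageRecord]
    quality: ProductQuality
    schedule: ScheduleResult
    cost_report: CostReport

    @property
    def annual_production_kg(self) -> float:
        return self.quality.amp_mass_per_batch_kg * self.plan.batches_per_year


def resolve_quantity(
    key: str, plan: UpstreamBatchPlan, stage_records: list[StageRecord]
) -> float:
    """Annual physical quantity behind a computed ledger line."""
    simple = {
        "annual_plants": float(plan.annual_plants),
        "annual_seed_mass_g": plan.annual_seed_mass_g,
        "annual_nutrient_demand_l": plan.annual_nutrient_demand_l,
        "annual_nutrient_waste_l": plan.annual_nutrient_waste_l,
        "annual_ethanol_solution_l": plan.annual_ethanol_solution_l,
    }
    if key in simple:
        return simple[key]
    if key.startswith("addition:"):
        added_name = key.split(":", 1)[1]
        per_batch = 0.0
        found = False
        for record in stage_records:
            if added_name in record.additions:
                per_batch += record.additions[added_name]
                found = True
        if not found:
            raise ConfigurationError(
                f"ledger references unknown added input {added_name!r}"
            )
        return per_batch * plan.batches_per_year
    raise ConfigurationError(f"unknown ledger quantity key {key!r}")


def resolve_ledger(
    config: ScenarioConfig,
    plan: UpstreamBatchPlan,
    stage_records: list[StageRecord],
    lump_scale: Mapping[str, float] = _NO_SCALE,
) -> list[CostItem]:
    """Turn the config ledger into resolved CostItems.

    ``lump_scale`` maps scaling rules ("biomass", "volume", "product",
    "fixed") to multipliers applied to lump-sum lines during facility
    re-design scans; computed lines rescale through their quantities instead.
    """
    items: list[CostItem] = []
    for cfg in config.ledger:
        if cfg.kind == "computed":
            qty = resolve_quantity(cfg.quantity_key, plan, stage_records)
            items.append(
                CostItem(
                    name=cfg.name,
                    section=cfg.section,
                    category=cfg.category,
                    operation=cfg.operation,
                    annual_quantity=qty,
                    unit_price=cfg.unit_price,
                    unit=cfg.unit,
                )
            )
        else:
            factor = lump_scale.get(cfg.scaling, 1.0)
            items.append(
                CostItem(
                    name=cfg.name,
                    section=cfg.section,
                    category=cfg.category,
                    operation=cfg.operation,
                    annual_quantity=1.0,
                    unit_price=cfg.annual_cost * factor,
                    unit="$/yr",
                )
            )
    return items


def resolve_equipment(
    config: ScenarioConfig, size_scale: Mapping[str, float] = _NO_SCALE
) -> list[EquipmentItem]:
    """Equipment list with actual sizes rescaled per sizing basis.

    Capacity is treated as continuous (no discrete unit duplication), so
    resized facilities move smoothly along the power-law cost curve.
    """
    resolved = []
    for cfg in config.equipment:
        factor = size_scale.get(cfg.sizing_basis, 1.0)
        resolved.append(
            EquipmentItem(
                name=cfg.name,
                section=cfg.section,
                reference_cost=cfg.reference_cost,
                reference_size=cfg.reference_size,
                actual_size=cfg.actual_size * factor,
                scaling_exponent=cfg.scaling_exponent,
                installation_multiplier=cfg.installation_multiplier,
                sizing_basis=cfg.sizing_basis,
            )
        )
    return resolved


def run_pipeline(
    config: ScenarioConfig,
    lump_scale: Mapping[str, float] = _NO_SCALE,
    size_scale: Mapping[str, float] = _NO_SCALE,
) -> ScenarioResult:
    """Execute the full scenario pipeline and return all results."""
    logger.info("scenario %s: sizing upstream batches", config.name)
    recovery = overall_recovery_from_config(config)
    plan = size_batches(
        annual_demand_kg=config.annual_demand_kg,
        overall_downstream_recovery=recovery,
        host=config.host,
        prices=config.prices,
        batches_per_year=config.schedule.batches_per_year,
    )
    logger.info(
        "scenario %s: propagating one %.0f kg FW batch through %d stages",
        config.name,
        plan.fw_per_batch_kg,
        len(config.chain),
    )
    records = run_downstream(config, plan.fw_per_batch_kg)
    for record in records:
        logger.debug("stage %s: %s", record.op_name, record.product_stream.to_dict())
    quality = quality_metrics(records)
    schedule = make_schedule(
        ScheduleInputs.from_config(config.schedule), plan.plants_per_batch
    )
    items = resolve_ledger(config, plan, records, lump_scale)
    equipment = resolve_equipment(config, size_scale)
    report = build_cost_report(equipment, items, config.annual_demand_kg)
    logger.info(
        "scenario %s: COGS $%.2f/g (AOC $%.3g/yr)", config.name, report.cogs_per_g, report.aoc
    )
    return ScenarioResult(
        config=config,
        plan=plan,
        stage_records=records,
        quality=quality,
        schedule=schedule,
        cost_report=report,
    )
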