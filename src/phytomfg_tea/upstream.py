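"""Upstream model: annual demand -> per-batch biomass, plants, trays, inputs.

The facility is sized backwards from demand: the downstream chain loses a
fixed fraction of the AMP, so upstream must grow ``demand / recovery`` worth
of product, which at the host's expression level fixes the fresh weight per
batch, and thence plant counts, trays, seed mass, nutrient volumes, and the
4% (v/v) ethanol induction solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import HostParamsConfig, PricesConfig
from .exceptions import EconomicsError


@dataclass
class UpstreamBatchPlan:
    """Per-batch and annual upstream demands for one scenario."""

    fw_per_batch_kg: float
    amp_per_batch_kg: float
    plants_per_batch: int
    trays_per_batch: int
    batches_per_year: int
    seed_mass_per_batch_g: float
    ethanol_solution_per_batch_l: float
    nutrient_demand_per_batch_l: float
    nutrient_waste_per_batch_l: float

    @property
    def annual_fw_kg(self) -> float:
        return self.fw_per_batch_kg * self.batches_per_year

    @property
    def annual_plants(self) -> int:
        return self.plants_per_batch * self.batches_per_year

    @property
    def annual_seed_mass_g(self) -> float:
        return self.seed_mass_per_batch_g * self.batches_per_year

    @property
    def annual_ethanol_solution_l(self) -> float:
        return self.ethanol_solution_per_batch_l * self.batches_per_year

    @property
    def annual_nutrient_demand_l(self) -> float:
        return self.nutrient_demand_per_batch_l * self.batches_per_year

    @property
    def annual_nutrient_waste_l(self) -> float:
        return self.nutrient_waste_per_batch_l * self.batches_per_year

    def to_dict(self) -> dict:
        return {
            "fw_per_batch_kg": self.fw_per_batch_kg,
            "amp_per_batch_kg": self.amp_per_batch_kg,
            "plants_per_batch": self.plants_per_batch,
            "trays_per_batch": self.trays_per_batch,
            "batches_per_year": self.batches_per_year,
            "annual_fw_kg": self.annual_fw_kg,
            "annual_plants": self.annual_plants,
            "annual_seed_mass_g": self.annual_seed_mass_g,
            "annual_ethanol_solution_l": self.annual_ethanol_solution_l,
            "annual_nutrient_demand_l": self.annual_nutrient_demand_l,
            "annual_nutrient_waste_l": self.annual_nutrient_waste_l,
        }


def fw_per_batch(
    annual_demand_kg: float,
    overall_downstream_recovery: float,
    expression_g_per_kg_fw: float,
    batches_per_year: int,
) -> float:
    """Fresh weight per batch required to meet *annual_demand_kg* of AMP.

    ``demand / recovery`` is the AMP that must be harvested annually; at
    E g AMP per kg FW that is ``1000 / E`` kg FW per kg AMP, split over the
    year's batches.
    """
    if annual_demand_kg <= 0:
        raise EconomicsError(f"annual demand must be > 0, got {annual_demand_kg}")
    if not 0 < overall_downstream_recovery <= 1:
        raise EconomicsError(
            f"downstream recovery must be in (0, 1], got {overall_downstream_recovery}"
        )
    if expression_g_per_kg_fw <= 0:
        raise EconomicsError(
            f"expression level must be > 0, got {expression_g_per_kg_fw}"
        )
    if batches_per_year < 1:
        raise EconomicsError(f"batches_per_year must be >= 1, got {batches_per_year}")
    annual_amp_upstream_kg = annual_demand_kg / overall_downstream_recovery
    annual_fw_kg = annual_amp_upstream_kg * 1000.0 / expression_g_per_kg_fw
    return annual_fw_kg / batches_per_year


def size_batches(
    annual_demand_kg: float,
    overall_downstream_recovery: float,
    host: HostParamsConfig,
    prices: PricesConfig,
    batches_per_year: int,
) -> UpstreamBatchPlan:
    """Build the full upstream demand plan for one scenario."""
    fw = fw_per_batch(
        annual_demand_kg,
        overall_downstream_recovery,
        host.expression_g_per_kg_fw,
        batches_per_year,
    )
    amp = fw * host.expression_g_per_kg_fw / 1000.0
    plants = math.ceil(fw / (host.fw_per_plant_at_harvest_g / 1000.0))
    if host.field_grown:
        # Direct field seeding: no trays; one seed sown per plant stand.
        trays = 0
        seed_mass_g = plants / prices.seeds_per_g
    else:
        trays = math.ceil(plants / host.plants_per_tray)
        seed_mass_g = trays * host.seeds_per_tray / prices.seeds_per_g
    return UpstreamBatchPlan(
        fw_per_batch_kg=fw,
        amp_per_batch_kg=amp,
        plants_per_batch=plants,
        trays_per_batch=trays,
        batches_per_year=batches_per_year,
        seed_mass_per_batch_g=seed_mass_g,
        ethanol_solution_per_batch_l=induction_demand_per_batch(fw, host),
        nutrient_demand_per_batch_l=fw * prices.nutrient_demand_l_per_kg_fw,
        nutrient_waste_per_batch_l=fw * prices.nutrient_waste_l_per_kg_fw,
    )


def induction_demand_per_batch(fw_per_batch_kg: float, host: HostParamsConfig) -> float:
    """Litres of 4% (v/v) ethanol solution per batch.

    The dose is 0.01 L per kg FW present at induction; plants are induced
    before the final incubation, when they carry ``induction_biomass_factor``
    of their harvest fresh weight.
    """
    factor = host.induction_biomass_factor
    if not 0 < factor <= 1:
        raise EconomicsError(
            f"induction_biomass_factor must be in (0, 1], got {factor}"
        )
    return 0.01 * fw_per_batch_kg * factor


def seed_cost_per_year(plan: UpstreamBatchPlan, prices: PricesConfig) -> float:
    """Annual seed cost in $ (seed mass priced per gram)."""
    return plan.annual_seed_mass_g * prices.seed_price_per_g
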