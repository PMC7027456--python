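"""Scenario configuration schema and YAML round-trip.

A :class:`ScenarioConfig` is the complete, self-contained description of one
facility scenario: host-plant parameters, harvest-stream composition, the
ordered downstream chain with its calibrated transfer coefficients, schedule
constants, the itemized cost ledger, and the equipment list.  Configs are
validated with pydantic and serialized to human-readable YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .exceptions import ConfigurationError

Section = Literal["upstream", "downstream"]
CostCategory = Literal[
    "raw_material", "consumable", "labor", "utility", "waste", "qc_qa", "other"
]
# How an annual cost line rescales in facility re-design scans:
#   biomass  - proportional to annual fresh weight / plant count
#   volume   - proportional to per-batch extract volume x batches
#   product  - proportional to annual product mass
#   fixed    - independent of scale (labor crews, QC program)
ScalingRule = Literal["biomass", "volume", "product", "fixed"]


class HostParamsConfig(BaseModel):
    name: str
    fw_per_plant_at_harvest_g: float = Field(gt=0)
    expression_g_per_kg_fw: float = Field(gt=0)
    tsp_fraction: float = Field(gt=0, le=1)
    seeds_per_tray: int = Field(gt=0)
    plants_per_tray: int = Field(gt=0)
    growth_days: float = Field(gt=0)
    incubation_days: float = Field(ge=0)
    has_alkaloid: bool
    induction_biomass_factor: float = Field(gt=0, le=1)
    field_grown: bool = False

    @model_validator(mode="after")
    def _tray_counts(self) -> "HostParamsConfig":
        if self.plants_per_tray > self.seeds_per_tray:
            raise ValueError("plants_per_tray cannot exceed seeds_per_tray")
        return self


class HarvestCompositionConfig(BaseModel):
    """Mass fractions of the harvested fresh weight besides AMP and water."""

    host_soluble_impurity_frac: float = Field(gt=0, lt=1)
    insoluble_solids_frac: float = Field(ge=0, lt=1)


class AddedInputConfig(BaseModel):
    name: str
    ratio: float = Field(ge=0)
    basis: str  # "input_total" or a component name
    composition: dict[str, float]


class UnitOpConfig(BaseModel):
    name: str
    product_transfer: dict[str, float]
    added_inputs: list[AddedInputConfig] = []
    sizing_basis: Literal["volume", "product_mass"] = "volume"


class ScheduleConfig(BaseModel):
    operating_days_per_year: float = Field(gt=0, le=365)
    upstream_cycle_days: float = Field(gt=0)
    downstream_cycle_days: float = Field(gt=0)
    batch_duration_days: float = Field(gt=0)
    batches_per_year: int = Field(ge=1)
    seasonal: bool = False


class CostItemConfig(BaseModel):
    """One annual cost line.

    ``kind="computed"`` lines price a physical quantity that the pipeline
    derives at run time (identified by ``quantity_key``); ``kind="lump"``
    lines carry a calibrated annual cost directly.
    """

    name: str
    section: Section
    category: CostCategory
    operation: str  # owning process operation, e.g. "seeding", "chromatography"
    kind: Literal["computed", "lump"]
    scaling: ScalingRule
    quantity_key: str | None = None
    unit: str = ""
    unit_price: float | None = Field(default=None, ge=0)
    annual_cost: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _kind_fields(self) -> "CostItemConfig":
        if self.kind == "computed":
            if self.quantity_key is None or self.unit_price is None:
                raise ValueError(
                    f"computed cost item {self.name!r} needs quantity_key and unit_price"
                )
        else:
            if self.annual_cost is None:
                raise ValueError(f"lump cost item {self.name!r} needs annual_cost")
        return self


class EquipmentItemConfig(BaseModel):
    name: str
    section: Section
    reference_cost: float = Field(gt=0)
    reference_size: float = Field(gt=0)
    actual_size: float = Field(gt=0)
    scaling_exponent: float = Field(gt=0, le=1)
    installation_multiplier: float = Field(gt=0)
    sizing_basis: Literal["biomass", "volume", "product_mass"]


class PricesConfig(BaseModel):
    """Unit prices and per-kg-FW consumption ratios for upstream materials."""

    substrate_per_plant: float = Field(ge=0)
    seed_price_per_g: float = Field(ge=0)
    seeds_per_g: float = Field(gt=0)
    nutrient_per_l: float = Field(ge=0)
    ethanol_solution_per_l: float = Field(ge=0)
    nutrient_demand_l_per_kg_fw: float = Field(ge=0)
    nutrient_waste_l_per_kg_fw: float = Field(ge=0)


class ScenarioConfig(BaseModel):
    name: str
    description: str = ""
    annual_demand_kg: float = Field(gt=0)
    host: HostParamsConfig
    harvest_composition: HarvestCompositionConfig
    chain: list[UnitOpConfig] = Field(min_length=1)
    schedule: ScheduleConfig
    prices: PricesConfig
    ledger: list[CostItemConfig]
    equipment: list[EquipmentItemConfig]
    alkaloid_clearance_op: str | None = None  # op asserted to clear host alkaloid

    @field_validator("ledger")
    @classmethod
    def _unique_item_names(cls, v: list[CostItemConfig]) -> list[CostItemConfig]:
        names = [item.name for item in v]
        if len(names) != len(set(names)):
            raise ValueError("ledger item names must be unique")
        return v

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            self.model_dump(mode="json"), sort_keys=False, default_flow_style=False
        )


def parse_config(path: str | Path) -> ScenarioConfig:
    """Load and schema-validate a scenario config file.

    Raises :class:`ConfigurationError` with field paths on schema violations
    and on malformed YAML (with line information from the YAML parser).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ScenarioConfig:
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid scenario config: {paths}") from exc


def write_config(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(config.to_yaml())
    return path
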