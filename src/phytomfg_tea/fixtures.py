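"""Reconstructed scenario configurations (base, spinach, field tobacco).

The original facility model was built in a commercial process simulator; its
full input set is not available, but the published per-batch stream table,
schedule constants, and cost aggregates pin down every coefficient the
engine needs.  This module performs that calibration in a fixed, documented
order and emits self-contained scenario configs:

1. mass balance - stage transfer coefficients solved from the per-batch
   stream masses and compositions (11,200 / 476 / 236 / 230 / 9.06 kg);
2. schedule - operating calendar and recipe cycle times as printed;
3. ledger - itemized annual costs under the published pins (substrate share,
   seeding-operation share, chromatography and UF/DF operation shares,
   downstream labor share, elution-buffer sensitivity), with the residual
   allocated to explicitly named remainder lines;
4. equipment - reference costs calibrated to the published per-section
   capital totals.

Later stages never alter earlier pins.  Randomized perturbations of a config
(for property tests) go through :func:`perturb_config`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import (
    AddedInputConfig,
    CostItemConfig,
    EquipmentItemConfig,
    HarvestCompositionConfig,
    HostParamsConfig,
    PricesConfig,
    ScenarioConfig,
    ScheduleConfig,
    UnitOpConfig,
    write_config,
)
from .downstream import harvest_stream, run_downstream
from .exceptions import ConfigurationError
from .flowsheet import AddedInput, Stream, UnitOpSpec, propagate
from .upstream import size_batches

SCENARIOS = ("base", "spinach", "tobacco")

# ---------------------------------------------------------------------------
# Calibration anchors: the published base-case batch.
# ---------------------------------------------------------------------------

ANNUAL_DEMAND_KG = 500.0
BASE_BATCHES = 91
BASE_FW_PER_BATCH = 9_520.0  # kg FW
BASE_EXPRESSION = 1.0  # g AMP / kg FW
TSP_FRACTION_OF_FW = 0.01  # total soluble protein is 1% of fresh weight
AMP_TSP_FRACTION = 0.10  # AMP is 10% of TSP
# Host soluble impurity = TSP - AMP = 0.9% of FW at the base expression level.
HOST_IMPURITY_FRAC_FW = TSP_FRACTION_OF_FW * (1.0 - AMP_TSP_FRACTION)
# Insoluble solids content of leafy biomass; not printed, only constrains the
# press-cake waste split (any plausible value closes the balance).
INSOLUBLE_FRAC_FW = 0.05

# Published per-batch stream table: (total kg, %AMP, %host impurity).
STREAM_TABLE = {
    "extraction": (11_200.0, 0.08, 0.61),
    "clarification_concentration": (476.0, 1.41, 0.83),
    "cation_exchange": (236.0, 2.48, 0.22),
    "diafiltration": (230.0, 2.38, 0.21),
}
FINAL_PRODUCT_MASS = 9.06  # kg spray-dried powder per batch
# Spray drying is lossless for solids; the diafiltration AMP transfer is
# calibrated (within 0.5% of the printed-composition ratio) so that
# 91 batches x per-batch AMP = 500 kg/yr exactly.
FINAL_AMP_PER_BATCH = ANNUAL_DEMAND_KG / BASE_BATCHES  # = 5.4945 kg
FINAL_IMPURITY_PER_BATCH = 0.0021 * 230.0  # printed DF composition, kept by dryer

EXTRACTION_BUFFER_RATIO = 0.5  # kg buffer per kg FW (aqueous streams at 1 kg/L)
EXTRACTION_BUFFER_SALTS = 0.01
ELUTION_RATIO = 300.0 / 476.0  # kg elution buffer per kg CEX feed
ELUTION_SALTS = 0.065  # 50 mM phosphate + 1 M NaCl
DIAFILTRATION_FACTOR = 3.0  # kg PBS diafiltrate per kg DF feed
PBS_SALTS = 0.0096

# Unit prices ($). Substrate sits within the printed "1.3 cents per plant"
# rounding and reproduces the printed 41.2% share of annual operating cost.
SUBSTRATE_PRICE_PER_PLANT = 0.01277
SEED_PRICE_PER_G = 9.50
SEEDS_PER_G = 9_500.0
NUTRIENT_PRICE_PER_L = 0.10
ETHANOL_SOLUTION_PRICE_PER_L = 0.50
EXTRACTION_BUFFER_PRICE_PER_KG = 0.485
ELUTION_BUFFER_PRICE_PER_KG = 1.7221
PBS_BUFFER_PRICE_PER_KG = 0.388

# Nutrient accounting: annual demand 1.30e6 L with 436,000 L to waste,
# stored as per-kg-FW ratios (the printed "23% plant uptake" is ambiguous
# about its denominator).
NUTRIENT_DEMAND_L_PER_KG_FW = 1.50
NUTRIENT_WASTE_L_PER_KG_FW = 0.503

# Ethanol induction: 0.01 L/kg FW at induction; the printed annual volume
# (7,410 L) against the annual harvest FW (866,000 kg) implies plants carry
# 85.5% of their harvest weight at induction.
INDUCTION_BIOMASS_FACTOR = 0.8553

# Host parameters. Per-plant harvest weights are back-derived from printed
# (FW/batch, plants/batch) pairs: 9,520 kg / 1.22e6 = 7.803 g for
# N. benthamiana; the spinach and field-tobacco values likewise.
FW_PER_PLANT = {"base": 7.803, "spinach": 7.70, "tobacco": 989.0}

# Published per-section cost aggregates used for ledger calibration.  The
# spinach and tobacco section totals follow the published per-gram COGS
# split (their printed OPEX rows disagree with it by <1%).
SECTION_OPEX_TARGETS = {
    "base": {"upstream": 2_010_000.0, "downstream": 1_430_000.0},
    "spinach": {"upstream": 1_760_000.0, "downstream": 700_000.0},
    "tobacco": {"upstream": 277_500.0, "downstream": 1_225_000.0},
}

# Installed equipment cost targets ($M) per scenario, by section.
EQUIPMENT_TABLES = {
    "base": {
        "upstream": [
            ("cultivation racks & LED lighting", 12.0, 1.5, "biomass", 1.0),
            ("HVAC & environmental control", 3.0, 1.5, "biomass", 1.0),
            ("hydroponic nutrient system", 2.0, 1.5, "biomass", 1.0),
            ("ethanol induction system", 0.8, 1.5, "biomass", 1.0),
            ("harvesters & conveyors", 1.3, 1.5, "biomass", 1.0),
        ],
        "downstream": [
            ("microfiltration skid", 7.6, 2.0, "volume", 26.0),
            ("ultrafiltration skid", 7.6, 2.0, "volume", 26.0),
            ("cation exchange system", 5.6, 2.0, "product_mass", 283.0),
            ("diafiltration skid", 2.8, 2.0, "volume", 1.0),
            ("spray dryer", 3.2, 2.0, "product_mass", 1.0),
            ("buffer prep & storage tanks", 1.6, 2.0, "volume", 1.0),
            ("disintegrator & screw press", 1.6, 2.0, "volume", 1.0),
            ("CIP/SIP skid", 1.0, 2.0, "volume", 1.0),
        ],
    },
    "spinach": {
        "upstream": [
            ("cultivation racks & LED lighting", 12.0, 1.5, "biomass", 1.0),
            ("HVAC & environmental control", 3.0, 1.5, "biomass", 1.0),
            ("hydroponic nutrient system", 2.0, 1.5, "biomass", 1.0),
            ("ethanol induction system", 0.8, 1.5, "biomass", 1.0),
            ("harvesters & conveyors", 1.3, 1.5, "biomass", 1.0),
        ],
        "downstream": [
            ("microfiltration skid", 7.6, 2.0, "volume", 26.0),
            ("ultrafiltration skid", 7.6, 2.0, "volume", 26.0),
            ("diafiltration skid", 4.0, 2.0, "volume", 1.0),
            ("spray dryer", 3.4, 2.0, "product_mass", 1.0),
            ("buffer prep & storage tanks", 1.8, 2.0, "volume", 1.0),
            ("disintegrator & screw press", 1.8, 2.0, "volume", 1.0),
            ("CIP/SIP skid", 1.2, 2.0, "volume", 1.0),
        ],
    },
    "tobacco": {
        "upstream": [
            ("field equipment (tractors, planters, harvesters)", 1.30, 1.2, "biomass", 1.0),
        ],
        "downstream": [
            ("microfiltration skid", 6.4, 2.0, "volume", 26.0),
            ("ultrafiltration skid", 6.4, 2.0, "volume", 26.0),
            ("cation exchange system", 5.0, 2.0, "product_mass", 283.0),
            ("diafiltration skid", 2.4, 2.0, "volume", 1.0),
            ("spray dryer", 2.8, 2.0, "product_mass", 1.0),
            ("buffer prep & storage tanks", 1.4, 2.0, "volume", 1.0),
            ("disintegrator & screw press", 1.4, 2.0, "volume", 1.0),
            ("CIP/SIP skid", 0.4, 2.0, "volume", 1.0),
        ],
    },
}

# Calibrated lump-sum ledger lines (annual $), named values chosen under the
# published pins; the per-section remainder goes to the residual line named
# last in each tuple list.  Downstream labor lines sum to 18.5% of the base
# annual operating cost.
_BASE_UPSTREAM_LUMPS = [
    ("seeding & transplant labor", "labor", "seeding", "biomass", 35_000.0),
    ("tray cleaning & seeding consumables", "consumable", "seeding", "biomass", 24_000.0),
    ("growth, induction & harvest labor", "labor", "plant_growth", "biomass", 229_000.0),
    ("upstream utilities (LED, HVAC, water)", "utility", "plant_growth", "biomass", 26_000.0),
    ("upstream QC & GACP program", "qc_qa", "quality", "fixed", 25_000.0),
]
_BASE_UPSTREAM_RESIDUAL = ("miscellaneous upstream operations", "other", "plant_growth", "biomass")

_BASE_DOWNSTREAM_LUMPS = [
    ("chromatography labor", "labor", "chromatography", "fixed", 340_000.0),
    ("UF/DF labor", "labor", "uf_df", "fixed", 251_400.0),
    ("extraction & formulation labor", "labor", "extraction_formulation", "fixed", 45_000.0),
    ("cation exchange resin", "consumable", "chromatography", "product", 150_000.0),
    ("TFF membranes", "consumable", "uf_df", "volume", 210_000.0),
    ("chromatography utilities", "utility", "chromatography", "product", 6_400.0),
    ("UF/DF utilities", "utility", "uf_df", "volume", 14_100.0),
    ("CIP/SIP chemicals", "raw_material", "extraction_formulation", "volume", 40_000.0),
    ("spray dryer utilities", "utility", "extraction_formulation", "product", 31_400.0),
    ("downstream QC & cGMP program", "qc_qa", "quality", "fixed", 35_000.0),
]
_BASE_DOWNSTREAM_RESIDUAL = ("biowaste disposal", "waste", "extraction_formulation", "volume")

_SPINACH_UPSTREAM_LUMPS = [
    ("seeding & transplant labor", "labor", "seeding", "biomass", 31_000.0),
    ("tray cleaning & seeding consumables", "consumable", "seeding", "biomass", 21_000.0),
    ("growth, induction & harvest labor", "labor", "plant_growth", "biomass", 180_000.0),
    ("upstream utilities (LED, HVAC, water)", "utility", "plant_growth", "biomass", 23_000.0),
    ("upstream QC & GACP program", "qc_qa", "quality", "fixed", 25_000.0),
]
_SPINACH_DOWNSTREAM_LUMPS = [
    ("UF/DF labor", "labor", "uf_df", "fixed", 149_000.0),
    ("extraction & formulation labor", "labor", "extraction_formulation", "fixed", 38_000.0),
    ("TFF membranes", "consumable", "uf_df", "volume", 170_000.0),
    ("UF/DF utilities", "utility", "uf_df", "volume", 12_000.0),
    ("CIP/SIP chemicals", "raw_material", "extraction_formulation", "volume", 30_000.0),
    ("spray dryer utilities", "utility", "extraction_formulation", "product", 27_000.0),
    ("downstream QC & cGMP program", "qc_qa", "quality", "fixed", 28_000.0),
]

_TOBACCO_UPSTREAM_LUMPS = [
    ("field operations labor", "labor", "field_growth", "biomass", 120_000.0),
    ("fertilizer & agrochemicals", "raw_material", "field_growth", "biomass", 60_000.0),
    ("field equipment fuel & maintenance", "utility", "field_growth", "biomass", 40_000.0),
    ("upstream QC & GACP program", "qc_qa", "quality", "fixed", 20_000.0),
]
_TOBACCO_UPSTREAM_RESIDUAL = ("miscellaneous field operations", "other", "field_growth", "biomass")
_TOBACCO_DOWNSTREAM_LUMPS = [
    ("chromatography labor", "labor", "chromatography", "fixed", 260_000.0),
    ("UF/DF labor", "labor", "uf_df", "fixed", 190_000.0),
    ("extraction & formulation labor", "labor", "extraction_formulation", "fixed", 38_000.0),
    ("cation exchange resin", "consumable", "chromatography", "product", 150_000.0),
    ("TFF membranes", "consumable", "uf_df", "volume", 210_000.0),
    ("chromatography utilities", "utility", "chromatography", "product", 6_400.0),
    ("UF/DF utilities", "utility", "uf_df", "volume", 14_100.0),
    ("CIP/SIP chemicals", "raw_material", "extraction_formulation", "volume", 25_000.0),
    ("spray dryer utilities", "utility", "extraction_formulation", "product", 20_000.0),
    ("downstream QC & cGMP program", "qc_qa", "quality", "fixed", 18_000.0),
]


# ---------------------------------------------------------------------------
# Stage 1: mass-balance calibration.
# ---------------------------------------------------------------------------

def _calibrated_base_ops() -> list[UnitOpConfig]:
    """Solve the base-case transfer coefficients from the stream table.

    AMP and impurity transfers follow directly from the printed stage masses
    and compositions; water and salts share one transfer fraction per stage
    (they co-permeate), solved so the stage's total product mass matches the
    table.  The final formulation buffer-salt content is set by closing the
    9.06 kg powder mass.
    """
    harvest = Stream(
        {
            "water": BASE_FW_PER_BATCH
            * (1 - BASE_EXPRESSION / 1000.0 - HOST_IMPURITY_FRAC_FW - INSOLUBLE_FRAC_FW),
            "amp": BASE_FW_PER_BATCH * BASE_EXPRESSION / 1000.0,
            "host_soluble_impurity": BASE_FW_PER_BATCH * HOST_IMPURITY_FRAC_FW,
            "insoluble_solids": BASE_FW_PER_BATCH * INSOLUBLE_FRAC_FW,
        }
    )

    def targets(stage: str) -> tuple[float, float, float]:
        total, amp_pct, imp_pct = STREAM_TABLE[stage]
        return total, total * amp_pct / 100.0, total * imp_pct / 100.0

    ops: list[UnitOpConfig] = []
    stream = harvest

    def solve_stage(
        name: str,
        added: list[AddedInputConfig],
        total_t: float,
        amp_t: float,
        imp_t: float,
        sizing_basis: str,
        salts_t: float | None = None,
    ) -> None:
        nonlocal stream
        combined = stream
        for a in added:
            combined = combined.plus(
                AddedInput(a.name, a.ratio, a.basis, a.composition).as_stream(stream)
            )
        transfer = {
            "amp": amp_t / combined.mass("amp"),
            "host_soluble_impurity": imp_t / combined.mass("host_soluble_impurity"),
            "insoluble_solids": 0.0,
        }
        if salts_t is None:
            # water and salts co-permeate with a shared fraction
            ws = combined.mass("water") + combined.mass("buffer_salts")
            f = (total_t - amp_t - imp_t) / ws
            transfer["water"] = f
            if combined.mass("buffer_salts") > 0:
                transfer["buffer_salts"] = f
        else:
            transfer["buffer_salts"] = salts_t / combined.mass("buffer_salts")
            transfer["water"] = (total_t - amp_t - imp_t - salts_t) / combined.mass("water")
        cfg = UnitOpConfig(
            name=name,
            product_transfer={k: round(v, 10) for k, v in transfer.items()},
            added_inputs=added,
            sizing_basis=sizing_basis,
        )
        ops.append(cfg)
        spec = UnitOpSpec(
            cfg.name,
            cfg.product_transfer,
            tuple(
                AddedInput(a.name, a.ratio, a.basis, a.composition)
                for a in cfg.added_inputs
            ),
            cfg.sizing_basis,
        )
        stream = propagate(spec, stream).product_stream

    solve_stage(
        "extraction",
        [
            AddedInputConfig(
                name="extraction_buffer",
                ratio=EXTRACTION_BUFFER_RATIO,
                basis="input_total",
                composition={
                    "water": 1 - EXTRACTION_BUFFER_SALTS,
                    "buffer_salts": EXTRACTION_BUFFER_SALTS,
                },
            )
        ],
        *targets("extraction"),
        sizing_basis="volume",
    )
    solve_stage(
        "clarification_concentration",
        [],
        *targets("clarification_concentration"),
        sizing_basis="volume",
    )
    solve_stage(
        "cation_exchange",
        [
            AddedInputConfig(
                name="elution_buffer",
                ratio=ELUTION_RATIO,
                basis="input_total",
                composition={"water": 1 - ELUTION_SALTS, "buffer_salts": ELUTION_SALTS},
            )
        ],
        *targets("cation_exchange"),
        sizing_basis="product_mass",
    )
    df_total, _, df_imp = STREAM_TABLE["diafiltration"]
    df_salts = FINAL_PRODUCT_MASS - FINAL_AMP_PER_BATCH - FINAL_IMPURITY_PER_BATCH
    solve_stage(
        "diafiltration",
        [
            AddedInputConfig(
                name="pbs_diafiltrate",
                ratio=DIAFILTRATION_FACTOR,
                basis="input_total",
                composition={"water": 1 - PBS_SALTS, "buffer_salts": PBS_SALTS},
            )
        ],
        df_total,
        FINAL_AMP_PER_BATCH,
        FINAL_IMPURITY_PER_BATCH,
        sizing_basis="volume",
        salts_t=df_salts,
    )
    ops.append(
        UnitOpConfig(
            name="spray_dry",
            product_transfer={
                "amp": 1.0,
                "host_soluble_impurity": 1.0,
                "buffer_salts": 1.0,
                "water": 0.0,
            },
            added_inputs=[],
            sizing_basis="product_mass",
        )
    )
    return ops


def _chain_for(scenario: str) -> list[UnitOpConfig]:
    ops = _calibrated_base_ops()
    if scenario == "spinach":
        # Nicotine-free host: the alkaloid-clearance chromatography step is
        # removed; all other stage coefficients carry over.
        ops = [op for op in ops if op.name != "cation_exchange"]
    elif scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    return ops


# ---------------------------------------------------------------------------
# Stages 2-4: schedule, ledger, equipment.
# ---------------------------------------------------------------------------

def _host_for(scenario: str) -> HostParamsConfig:
    common = dict(
        expression_g_per_kg_fw=BASE_EXPRESSION,
        tsp_fraction=AMP_TSP_FRACTION,
        seeds_per_tray=94,
        plants_per_tray=94,
        induction_biomass_factor=INDUCTION_BIOMASS_FACTOR,
    )
    if scenario == "base":
        return HostParamsConfig(
            name="Nicotiana benthamiana",
            fw_per_plant_at_harvest_g=FW_PER_PLANT["base"],
            growth_days=35,
            incubation_days=6,
            has_alkaloid=True,
            **common,
        )
    if scenario == "spinach":
        return HostParamsConfig(
            name="Spinacia oleracea",
            fw_per_plant_at_harvest_g=FW_PER_PLANT["spinach"],
            growth_days=35,
            incubation_days=6,
            has_alkaloid=False,
            **common,
        )
    return HostParamsConfig(
        name="Nicotiana tabacum (field grown)",
        fw_per_plant_at_harvest_g=FW_PER_PLANT["tobacco"],
        growth_days=82.4,
        incubation_days=6,
        has_alkaloid=True,
        field_grown=True,
        **common,
    )


def _schedule_for(scenario: str) -> ScheduleConfig:
    if scenario == "tobacco":
        # Outdoor campaign packed into the late-March to late-October
        # growing season of the US Midwest/South (~214 days).
        return ScheduleConfig(
            operating_days_per_year=214.0,
            upstream_cycle_days=88.4,
            downstream_cycle_days=1.08,
            batch_duration_days=89.5,
            batches_per_year=63,
            seasonal=True,
        )
    downstream_cycle = 0.91 if scenario == "base" else 0.67
    return ScheduleConfig(
        operating_days_per_year=329.0,
        upstream_cycle_days=41.4,
        downstream_cycle_days=downstream_cycle,
        batch_duration_days=42.3,
        batches_per_year=BASE_BATCHES,
        seasonal=False,
    )


def _prices_for(scenario: str) -> PricesConfig:
    if scenario == "tobacco":
        # Field growth: no soilless substrate or hydroponic nutrient loop.
        return PricesConfig(
            substrate_per_plant=0.0,
            seed_price_per_g=SEED_PRICE_PER_G,
            seeds_per_g=SEEDS_PER_G,
            nutrient_per_l=0.0,
            ethanol_solution_per_l=ETHANOL_SOLUTION_PRICE_PER_L,
            nutrient_demand_l_per_kg_fw=0.0,
            nutrient_waste_l_per_kg_fw=0.0,
        )
    return PricesConfig(
        substrate_per_plant=SUBSTRATE_PRICE_PER_PLANT,
        seed_price_per_g=SEED_PRICE_PER_G,
        seeds_per_g=SEEDS_PER_G,
        nutrient_per_l=NUTRIENT_PRICE_PER_L,
        ethanol_solution_per_l=ETHANOL_SOLUTION_PRICE_PER_L,
        nutrient_demand_l_per_kg_fw=NUTRIENT_DEMAND_L_PER_KG_FW,
        nutrient_waste_l_per_kg_fw=NUTRIENT_WASTE_L_PER_KG_FW,
    )


def _computed_items_for(scenario: str) -> list[CostItemConfig]:
    items = []
    if scenario != "tobacco":
        items += [
            CostItemConfig(
                name="soilless plant substrate",
                section="upstream",
                category="consumable",
                operation="seeding",
                kind="computed",
                scaling="biomass",
                quantity_key="annual_plants",
                unit="plant",
                unit_price=SUBSTRATE_PRICE_PER_PLANT,
            ),
            CostItemConfig(
                name="nutrient solution",
                section="upstream",
                category="raw_material",
                operation="plant_growth",
                kind="computed",
                scaling="biomass",
                quantity_key="annual_nutrient_demand_l",
                unit="L",
                unit_price=NUTRIENT_PRICE_PER_L,
            ),
        ]
    items += [
        CostItemConfig(
            name="transgenic seed",
            section="upstream",
            category="raw_material",
            operation="seeding" if scenario != "tobacco" else "field_growth",
            kind="computed",
            scaling="biomass",
            quantity_key="annual_seed_mass_g",
            unit="g",
            unit_price=SEED_PRICE_PER_G,
        ),
        CostItemConfig(
            name="ethanol induction solution (4% v/v)",
            section="upstream",
            category="raw_material",
            operation="induction",
            kind="computed",
            scaling="biomass",
            quantity_key="annual_ethanol_solution_l",
            unit="L",
            unit_price=ETHANOL_SOLUTION_PRICE_PER_L,
        ),
        CostItemConfig(
            name="extraction buffer",
            section="downstream",
            category="raw_material",
            operation="extraction_formulation",
            kind="computed",
            scaling="volume",
            quantity_key="addition:extraction_buffer",
            unit="kg",
            unit_price=EXTRACTION_BUFFER_PRICE_PER_KG,
        ),
        CostItemConfig(
            name="diafiltration buffer (PBS)",
            section="downstream",
            category="raw_material",
            operation="uf_df",
            kind="computed",
            scaling="volume",
            quantity_key="addition:pbs_diafiltrate",
            unit="kg",
            unit_price=PBS_BUFFER_PRICE_PER_KG,
        ),
    ]
    if scenario != "spinach":
        items.append(
            CostItemConfig(
                name="chromatography elution buffer",
                section="downstream",
                category="raw_material",
                operation="chromatography",
                kind="computed",
                scaling="product",
                quantity_key="addition:elution_buffer",
                unit="kg",
                unit_price=ELUTION_BUFFER_PRICE_PER_KG,
            )
        )
    return items


def _lump(name, section, category, operation, scaling, annual_cost) -> CostItemConfig:
    return CostItemConfig(
        name=name,
        section=section,
        category=category,
        operation=operation,
        kind="lump",
        scaling=scaling,
        annual_cost=round(annual_cost, 2),
    )


def _equipment_for(scenario: str) -> list[EquipmentItemConfig]:
    items = []
    for section, rows in EQUIPMENT_TABLES[scenario].items():
        for name, installed_m, multiplier, basis, size in rows:
            items.append(
                EquipmentItemConfig(
                    name=name,
                    section=section,
                    reference_cost=installed_m * 1e6 / multiplier,
                    reference_size=size,
                    actual_size=size,
                    scaling_exponent=0.6,
                    installation_multiplier=multiplier,
                    sizing_basis=basis,
                )
            )
    return items


def emit_config(scenario: str, path: str | Path | None = None) -> ScenarioConfig:
    """Build the calibrated scenario config; optionally write it as YAML.

    Emission is deterministic: the same scenario name always yields a
    byte-identical file.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    chain = _chain_for(scenario)
    host = _host_for(scenario)
    schedule = _schedule_for(scenario)
    prices = _prices_for(scenario)
    computed_items = _computed_items_for(scenario)

    descriptions = {
        "base": "Indoor N. benthamiana base case: 500 kg AMP/yr at 1 g/kg FW, "
        "cation-exchange nicotine clearance, 91 batches/yr.",
        "spinach": "Indoor nicotine-free S. oleracea: chromatography step removed, "
        "66% overall recovery, 63% purity.",
        "tobacco": "Outdoor field-grown N. tabacum: 63 seasonal batches, "
        "dedicated transgenic field equipment.",
    }

    # Provisional config (empty ledger) to resolve computed quantities.
    provisional = ScenarioConfig(
        name=scenario,
        description=descriptions[scenario],
        annual_demand_kg=ANNUAL_DEMAND_KG,
        host=host,
        harvest_composition=HarvestCompositionConfig(
            host_soluble_impurity_frac=HOST_IMPURITY_FRAC_FW,
            insoluble_solids_frac=INSOLUBLE_FRAC_FW,
        ),
        chain=chain,
        schedule=schedule,
        prices=prices,
        ledger=computed_items,
        equipment=_equipment_for(scenario),
        alkaloid_clearance_op="cation_exchange" if host.has_alkaloid else None,
    )
    # Resolve the computed lines once to allocate the per-section residual.
    from .pipeline import resolve_ledger  # local import avoids cycle at import time

    recovery = 1.0
    for op in chain:
        recovery *= op.product_transfer.get("amp", 0.0)
    plan = size_batches(
        ANNUAL_DEMAND_KG, recovery, host, prices, schedule.batches_per_year
    )
    records = run_downstream(provisional, plan.fw_per_batch_kg)
    computed_cost = {"upstream": 0.0, "downstream": 0.0}
    for item in resolve_ledger(provisional, plan, records):
        computed_cost[item.section] += item.annual_cost

    lumps = {
        "base": (
            _BASE_UPSTREAM_LUMPS,
            _BASE_UPSTREAM_RESIDUAL,
            _BASE_DOWNSTREAM_LUMPS,
            _BASE_DOWNSTREAM_RESIDUAL,
        ),
        "spinach": (
            _SPINACH_UPSTREAM_LUMPS,
            _BASE_UPSTREAM_RESIDUAL,
            _SPINACH_DOWNSTREAM_LUMPS,
            _BASE_DOWNSTREAM_RESIDUAL,
        ),
        "tobacco": (
            _TOBACCO_UPSTREAM_LUMPS,
            _TOBACCO_UPSTREAM_RESIDUAL,
            _TOBACCO_DOWNSTREAM_LUMPS,
            _BASE_DOWNSTREAM_RESIDUAL,
        ),
    }[scenario]
    up_lumps, up_residual, down_lumps, down_residual = lumps
    targets = SECTION_OPEX_TARGETS[scenario]

    ledger = list(computed_items)
    for name, category, operation, scaling, cost in up_lumps:
        ledger.append(_lump(name, "upstream", category, operation, scaling, cost))
    up_res_cost = (
        targets["upstream"]
        - computed_cost["upstream"]
        - sum(row[4] for row in up_lumps)
    )
    if up_res_cost < 0:
        raise ConfigurationError(
            f"{scenario}: upstream residual is negative ({up_res_cost:.0f})"
        )
    ledger.append(_lump(*up_residual[:1], "upstream", *up_residual[1:], up_res_cost))
    for name, category, operation, scaling, cost in down_lumps:
        ledger.append(_lump(name, "downstream", category, operation, scaling, cost))
    down_res_cost = (
        targets["downstream"]
        - computed_cost["downstream"]
        - sum(row[4] for row in down_lumps)
    )
    if down_res_cost < 0:
        raise ConfigurationError(
            f"{scenario}: downstream residual is negative ({down_res_cost:.0f})"
        )
    ledger.append(
        _lump(*down_residual[:1], "downstream", *down_residual[1:], down_res_cost)
    )

    config = provisional.model_copy(update={"ledger": ledger})
    if path is not None:
        write_config(config, path)
    return config


# ---------------------------------------------------------------------------
# Manifest, consistency validation, random perturbation.
# ---------------------------------------------------------------------------

@dataclass
class FixtureManifest:
    scenario: str
    calibration_notes: list[str]
    checksum_sha256: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "calibration_notes": self.calibration_notes,
                "checksum_sha256": self.checksum_sha256,
            },
            indent=2,
        )


_CALIBRATION_NOTES = {
    "base": [
        "PUBLISHED: 500 kg/yr demand, 1 g/kg FW expression, 91 batches, 329 operating days",
        "PUBLISHED: per-batch streams 11,200/476/236/230 kg and final 9.06 kg powder",
        "PUBLISHED: 9,520 kg FW and 9.52 kg AMP per batch; AMP = 10% of TSP",
        "PUBLISHED: section aggregates CAPEX 19.1/31.0 $M, OPEX 2.01/1.43 $M/yr",
        "PUBLISHED: substrate 41.2% of AOC at ~1.3 c/plant; seeding op 79% of upstream OPEX",
        "PUBLISHED: chromatography 38% and UF/DF 35% of downstream OPEX; downstream labor 18.5% of AOC",
        "PUBLISHED: elution buffer is the 10th cost item; +-30% price moves COGS +-0.41%",
        "DERIVED: stage transfer coefficients solved from stream table compositions",
        "DERIVED: diafiltration AMP transfer 5.4945/5.8528 closes 91 x batch = 500 kg/yr",
        "DERIVED: induction biomass factor 0.8553 = 7,410 L / (0.01 x 866,320 kg)",
        "DERIVED: 7.803 g FW/plant = 9,520 kg / 1.22e6 plants",
        "DERIVED: formulation salts 3.08 kg/batch close the 9.06 kg powder mass",
        "ASSUMED: insoluble solids 5% of FW; aqueous streams at 1.00 kg/L",
        "ALLOCATED: per-section ledger residual to named remainder lines",
    ],
    "spinach": [
        "PUBLISHED: chromatography step absent; 66% recovery and 63% purity emerge from the base coefficients",
        "PUBLISHED: COGS split 3.52/1.40 $/g pins section OPEX 1.76/0.70 $M/yr",
        "PUBLISHED: downstream cycle 0.67 d; ~1.08e6 plants/batch",
        "DERIVED: 7.70 g FW/plant from printed plants-per-batch at 66% recovery",
        "ALLOCATED: ledger lumps re-calibrated to spinach section totals",
    ],
    "tobacco": [
        "PUBLISHED: 63 seasonal batches, upstream cycle 88.4 d, downstream 1.08 d",
        "PUBLISHED: COGS split 0.555/2.45 $/g pins section OPEX 0.2775/1.225 $M/yr",
        "PUBLISHED: CAPEX 1.30/26.2 $M; 13,900 plants/batch",
        "DERIVED: 989 g FW/plant from printed plants-per-batch at base-chain recovery",
        "DERIVED: base-case stage recoveries reused (overall 57.7% prints as 58%)",
    ],
}


def fixture_manifest(scenario: str) -> FixtureManifest:
    config = emit_config(scenario)
    checksum = hashlib.sha256(config.to_yaml().encode()).hexdigest()
    return FixtureManifest(
        scenario=scenario,
        calibration_notes=list(_CALIBRATION_NOTES[scenario]),
        checksum_sha256=checksum,
    )


def validate_consistency(config: ScenarioConfig) -> list[str]:
    """Cross-check a config's content rules; returns violations, never raises.

    Structural/type validity is the schema's job; this checks the physical
    and economic relations a well-formed config must satisfy.
    """
    violations: list[str] = []
    for i, op in enumerate(config.chain):
        for comp, frac in op.product_transfer.items():
            if not 0.0 <= frac <= 1.0:
                violations.append(
                    f"chain[{i}].product_transfer.{comp}: fraction {frac} outside [0, 1]"
                )
        for j, added in enumerate(op.added_inputs):
            if added.ratio < 0:
                violations.append(
                    f"chain[{i}].added_inputs[{j}].ratio: negative ratio {added.ratio}"
                )
            comp_sum = sum(added.composition.values())
            if abs(comp_sum - 1.0) > 1e-6:
                violations.append(
                    f"chain[{i}].added_inputs[{j}].composition: sums to {comp_sum}, not 1"
                )
    if not any(op.product_transfer.get("amp", 0.0) > 0 for op in config.chain):
        violations.append("chain: no stage transfers any AMP to product")

    host = config.host
    if not 0 < host.induction_biomass_factor <= 1:
        violations.append(
            f"host.induction_biomass_factor: {host.induction_biomass_factor} outside (0, 1]"
        )
    if host.expression_g_per_kg_fw <= 0:
        violations.append("host.expression_g_per_kg_fw: must be > 0")
    if host.fw_per_plant_at_harvest_g <= 0:
        violations.append("host.fw_per_plant_at_harvest_g: must be > 0")

    hc = config.harvest_composition
    solids = (
        config.host.expression_g_per_kg_fw / 1000.0
        + hc.host_soluble_impurity_frac
        + hc.insoluble_solids_frac
    )
    if solids >= 1:
        violations.append(
            f"harvest_composition: solids fractions sum to {solids:.3f} >= 1"
        )

    sched = config.schedule
    if sched.seasonal:
        window = sched.operating_days_per_year - sched.upstream_cycle_days
        stagger = window / max(sched.batches_per_year - 1, 1) if window > 0 else 0.0
        if window <= 0:
            violations.append(
                "schedule: upstream cycle does not fit in the seasonal window"
            )
    else:
        stagger = sched.operating_days_per_year / sched.batches_per_year
    if stagger and sched.downstream_cycle_days > stagger:
        violations.append(
            f"schedule.downstream_cycle_days: {sched.downstream_cycle_days} d exceeds "
            f"the {stagger:.3g} d stagger (downstream collision)"
        )

    known_keys = {
        "annual_plants",
        "annual_seed_mass_g",
        "annual_nutrient_demand_l",
        "annual_nutrient_waste_l",
        "annual_ethanol_solution_l",
    }
    added_names = {a.name for op in config.chain for a in op.added_inputs}
    for i, item in enumerate(config.ledger):
        if item.kind == "computed":
            key = item.quantity_key or ""
            if key.startswith("addition:"):
                if key.split(":", 1)[1] not in added_names:
                    violations.append(
                        f"ledger[{i}].quantity_key: unknown added input {key!r}"
                    )
            elif key not in known_keys:
                violations.append(f"ledger[{i}].quantity_key: unknown key {key!r}")
            if item.unit_price is not None and item.unit_price < 0:
                violations.append(f"ledger[{i}].unit_price: negative")
        elif item.annual_cost is not None and item.annual_cost < 0:
            violations.append(f"ledger[{i}].annual_cost: negative")
    for i, eq in enumerate(config.equipment):
        if not 0 < eq.scaling_exponent <= 1:
            violations.append(
                f"equipment[{i}].scaling_exponent: {eq.scaling_exponent} outside (0, 1]"
            )
    return violations


# Numeric leaves eligible for random perturbation, as (path, getter, setter)
# implemented over the model's dict form.
def perturb_config(
    config: ScenarioConfig, seed: int, magnitude: float
) -> ScenarioConfig:
    """Multiply selected numeric parameters by factors in [1-m, 1+m].

    Reproducible for a given seed; magnitude 0 returns an identical config.
    Perturbed fields: host expression level and per-plant weight, unit
    prices, lump annual costs, chain transfer fractions and added-input
    ratios.  Perturbation can push transfer fractions past 1 - that is
    intentional, so consistency validation has something to catch.
    """
    if not 0.0 <= magnitude <= 0.5:
        raise ConfigurationError(f"magnitude must be in [0, 0.5], got {magnitude}")
    rng = np.random.default_rng(seed)
    raw = config.model_dump(mode="json")

    def jitter(value: float) -> float:
        return value * (1.0 + magnitude * rng.uniform(-1.0, 1.0))

    raw["host"]["expression_g_per_kg_fw"] = jitter(raw["host"]["expression_g_per_kg_fw"])
    raw["host"]["fw_per_plant_at_harvest_g"] = jitter(
        raw["host"]["fw_per_plant_at_harvest_g"]
    )
    for key, value in raw["prices"].items():
        raw["prices"][key] = jitter(value)
    for op in raw["chain"]:
        for comp in op["product_transfer"]:
            op["product_transfer"][comp] = jitter(op["product_transfer"][comp])
        for added in op["added_inputs"]:
            added["ratio"] = jitter(added["ratio"])
    for item in raw["ledger"]:
        if item["kind"] == "lump":
            item["annual_cost"] = jitter(item["annual_cost"])
        else:
            item["unit_price"] = jitter(item["unit_price"])
    return ScenarioConfig.model_validate(raw)
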