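"""Downstream model: concrete purification chains and product quality metrics.

Builds the per-scenario unit-operation chain (extraction, clarification /
concentration by MF+UF, optional cation-exchange capture, diafiltration,
spray drying) from a scenario config, constructs the harvest stream, and
summarizes a propagated batch into product quality figures.

"Purity" throughout is protein-basis: AMP over AMP-plus-host-soluble-protein
in the final powder.  The powder also carries formulation buffer salts, so
its AMP mass fraction (~61%) is much lower than its protein-basis purity
(~92%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .config import ScenarioConfig, UnitOpConfig
from .exceptions import ConfigurationError, FlowsheetValidationError
from .flowsheet import (
    AddedInput,
    StageRecord,
    Stream,
    UnitOpSpec,
    chain_amp_recovery,
    cumulative_recovery,
    run_chain,
)


@dataclass
class ProductQuality:
    formulated_mass_per_batch_kg: float
    amp_mass_per_batch_kg: float
    impurity_mass_per_batch_kg: float
    protein_basis_purity_pct: float
    overall_recovery: float

    def to_dict(self) -> dict:
        return {
            "formulated_mass_per_batch_kg": self.formulated_mass_per_batch_kg,
            "amp_mass_per_batch_kg": self.amp_mass_per_batch_kg,
            "impurity_mass_per_batch_kg": self.impurity_mass_per_batch_kg,
            "protein_basis_purity_pct": self.protein_basis_purity_pct,
            "overall_recovery": self.overall_recovery,
        }


def op_from_config(op_cfg: UnitOpConfig) -> UnitOpSpec:
    return UnitOpSpec(
        name=op_cfg.name,
        product_transfer=dict(op_cfg.product_transfer),
        added_inputs=tuple(
            AddedInput(
                name=a.name,
                ratio=a.ratio,
                basis=a.basis,
                composition=dict(a.composition),
            )
            for a in op_cfg.added_inputs
        ),
        sizing_basis=op_cfg.sizing_basis,
    )


def build_chain(config: ScenarioConfig) -> list[UnitOpSpec]:
    """The scenario's ordered downstream chain as engine unit ops."""
    return [op_from_config(op_cfg) for op_cfg in config.chain]


def overall_recovery_from_config(config: ScenarioConfig) -> float:
    """Overall AMP recovery implied by the chain's transfer coefficients."""
    return chain_amp_recovery(build_chain(config))


def harvest_stream(config: ScenarioConfig, fw_per_batch_kg: float) -> Stream:
    """Harvested-biomass stream for one batch.

    AMP mass follows from the expression level; host soluble impurity and
    insoluble solids are fixed fractions of fresh weight; water closes the
    balance (all aqueous material treated at 1.00 kg/L).
    """
    amp = fw_per_batch_kg * config.host.expression_g_per_kg_fw / 1000.0
    impurity = fw_per_batch_kg * config.harvest_composition.host_soluble_impurity_frac
    insoluble = fw_per_batch_kg * config.harvest_composition.insoluble_solids_frac
    water = fw_per_batch_kg - amp - impurity - insoluble
    if water < 0:
        raise FlowsheetValidationError(
            "harvest composition fractions exceed 1: no water left in biomass"
        )
    return Stream(
        {
            "water": water,
            "amp": amp,
            "host_soluble_impurity": impurity,
            "insoluble_solids": insoluble,
        },
        phase_label="harvested biomass",
    )


def run_downstream(config: ScenarioConfig, fw_per_batch_kg: float) -> list[StageRecord]:
    """Propagate one batch of *fw_per_batch_kg* through the scenario chain."""
    return run_chain(build_chain(config), harvest_stream(config, fw_per_batch_kg))


def quality_metrics(records: Sequence[StageRecord]) -> ProductQuality:
    """Final-product quality summary for a completed batch propagation."""
    if not records:
        raise ConfigurationError("quality metrics need at least one stage record")
    final = records[-1].product_stream
    if final.total_mass <= 0:
        raise FlowsheetValidationError("final product stream has zero mass")
    amp = final.mass("amp")
    impurity = final.mass("host_soluble_impurity")
    harvested_amp = records[0].input_stream.mass("amp")
    if amp + impurity <= 0:
        raise FlowsheetValidationError("final product contains no protein")
    return ProductQuality(
        formulated_mass_per_batch_kg=final.total_mass,
        amp_mass_per_batch_kg=amp,
        impurity_mass_per_batch_kg=impurity,
        protein_basis_purity_pct=100.0 * amp / (amp + impurity),
        overall_recovery=cumulative_recovery(records)
        if harvested_amp > 0
        else 1.0,
    )
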