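"""Cost accounting: CAPEX from the equipment list, itemized OPEX, COGS.

CAPEX uses power-law equipment scaling (cost = reference x (size ratio)^b x
installation multiplier, b defaulting to the six-tenths rule for resized
items).  OPEX is a flat rollup of the resolved annual cost ledger by section
and category.  COGS is annual operating cost over annual product mass; CAPEX
depreciation is deliberately excluded from COGS and reported separately,
matching the way the scenario summary table separates the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import EconomicsError

DEFAULT_SCALING_EXPONENT = 0.6


@dataclass(frozen=True)
class EquipmentItem:
    name: str
    section: str  # "upstream" | "downstream"
    reference_cost: float
    reference_size: float
    actual_size: float
    scaling_exponent: float = DEFAULT_SCALING_EXPONENT
    installation_multiplier: float = 1.0
    sizing_basis: str = "volume"

    def installed_cost(self) -> float:
        if self.reference_cost <= 0 or self.reference_size <= 0:
            raise EconomicsError(
                f"equipment {self.name!r}: reference cost/size must be > 0"
            )
        if self.actual_size <= 0:
            raise EconomicsError(f"equipment {self.name!r}: nonpositive size")
        if not 0 < self.scaling_exponent <= 1:
            raise EconomicsError(
                f"equipment {self.name!r}: scaling exponent must be in (0, 1]"
            )
        ratio = self.actual_size / self.reference_size
        return (
            self.reference_cost
            * ratio**self.scaling_exponent
            * self.installation_multiplier
        )


@dataclass(frozen=True)
class CostItem:
    """One resolved annual cost line (annual_cost = quantity x unit price)."""

    name: str
    section: str
    category: str
    operation: str
    annual_quantity: float
    unit_price: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.annual_quantity < 0 or self.unit_price < 0:
            raise EconomicsError(
                f"cost item {self.name!r}: quantity and price must be >= 0"
            )

    @property
    def annual_cost(self) -> float:
        return self.annual_quantity * self.unit_price


@dataclass
class CostReport:
    """Scenario cost rollup: CAPEX / OPEX by section, AOC, per-gram COGS."""

    capex_by_section: dict[str, float]
    opex_by_section: dict[str, float]
    opex_by_category: dict[str, float]
    opex_by_section_and_category: dict[tuple[str, str], float]
    aoc: float
    annual_demand_kg: float
    cogs_per_g: float
    cogs_split: dict[str, float]
    items: list[CostItem] = field(default_factory=list)

    @property
    def capex_total(self) -> float:
        return sum(self.capex_by_section.values())

    def section_shares_pct(self) -> dict[str, float]:
        return {k: 100.0 * v / self.aoc for k, v in self.opex_by_section.items()}

    def category_shares_pct(self) -> dict[str, float]:
        return {k: 100.0 * v / self.aoc for k, v in self.opex_by_category.items()}

    def item_share_pct(self, name: str) -> float:
        return 100.0 * self.item(name).annual_cost / self.aoc

    def item(self, name: str) -> CostItem:
        for item in self.items:
            if item.name == name:
                return item
        raise EconomicsError(
            f"no ledger item named {name!r}; ledger has: "
            + ", ".join(i.name for i in self.items)
        )

    def operation_cost(self, operation: str) -> float:
        return sum(i.annual_cost for i in self.items if i.operation == operation)

    def top_items(self, n: int = 10) -> list[CostItem]:
        return sorted(self.items, key=lambda i: i.annual_cost, reverse=True)[:n]

    def straight_line_depreciation(self, lifetime_years: float = 20.0) -> float:
        """Optional report line; never folded into COGS."""
        return self.capex_total / lifetime_years

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item": i.name,
                    "section": i.section,
                    "category": i.category,
                    "operation": i.operation,
                    "annual_quantity": i.annual_quantity,
                    "unit": i.unit,
                    "unit_price": i.unit_price,
                    "annual_cost": i.annual_cost,
                }
                for i in self.items
            ]
        ).sort_values("annual_cost", ascending=False, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "capex_by_section": dict(self.capex_by_section),
            "capex_total": self.capex_total,
            "opex_by_section": dict(self.opex_by_section),
            "opex_by_category": dict(self.opex_by_category),
            "aoc": self.aoc,
            "annual_demand_kg": self.annual_demand_kg,
            "cogs_per_g": self.cogs_per_g,
            "cogs_split": dict(self.cogs_split),
            "section_shares_pct": self.section_shares_pct(),
            "category_shares_pct": self.category_shares_pct(),
        }


def capex(equipment: Sequence[EquipmentItem]) -> dict[str, float]:
    """Installed capital cost by facility section."""
    if not equipment:
        raise EconomicsError("equipment list is empty")
    by_section: dict[str, float] = {}
    for item in equipment:
        by_section[item.section] = by_section.get(item.section, 0.0) + item.installed_cost()
    return by_section


def opex(items: Sequence[CostItem]) -> tuple[dict, dict, dict, float]:
    """Annual operating cost rollup.

    Returns (by_section, by_category, by_section_and_category, aoc) with
    deterministic (insertion-then-name) ordering.
    """
    by_section: dict[str, float] = {}
    by_category: dict[str, float] = {}
    by_both: dict[tuple[str, str], float] = {}
    for item in items:
        by_section[item.section] = by_section.get(item.section, 0.0) + item.annual_cost
        by_category[item.category] = (
            by_category.get(item.category, 0.0) + item.annual_cost
        )
        key = (item.section, item.category)
        by_both[key] = by_both.get(key, 0.0) + item.annual_cost
    aoc = sum(by_section.values())
    return by_section, by_category, by_both, aoc


def cogs(
    aoc: float, annual_demand_kg: float, opex_by_section: Mapping[str, float]
) -> tuple[float, dict[str, float]]:
    """Per-gram cost of goods sold and its upstream/downstream split ($/g)."""
    if annual_demand_kg <= 0:
        raise EconomicsError(f"annual demand must be > 0, got {annual_demand_kg}")
    grams = annual_demand_kg * 1000.0
    return aoc / grams, {k: v / grams for k, v in opex_by_section.items()}


def build_cost_report(
    equipment: Sequence[EquipmentItem],
    items: Sequence[CostItem],
    annual_demand_kg: float,
) -> CostReport:
    by_section, by_category, by_both, aoc = opex(items)
    cogs_per_g, split = cogs(aoc, annual_demand_kg, by_section)
    return CostReport(
        capex_by_section=capex(equipment),
        opex_by_section=by_section,
        opex_by_category=by_category,
        opex_by_section_and_category=by_both,
        aoc=aoc,
        annual_demand_kg=annual_demand_kg,
        cogs_per_g=cogs_per_g,
        cogs_split=split,
        items=list(items),
    )
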