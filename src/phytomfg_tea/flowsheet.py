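"""Batch flowsheet engine: component streams and unit-operation propagation.

A :class:`Stream` is a bag of component masses (kg per batch).  A
:class:`UnitOpSpec` describes one processing step as (a) zero or more added
inputs (buffers, diafiltrate), each a fixed mass ratio against a declared
basis with its own component composition, and (b) a per-component transfer
fraction into the product stream.  Whatever is not transferred leaves in the
waste stream, so every stage conserves mass component-wise:

    input + additions = product + waste

Chaining stages gives the whole downstream train; the cumulative product
(AMP) recovery is the product of the per-stage recoveries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, FlowsheetValidationError

# Component taxonomy: the smallest set that expresses every stream
# composition tracked by the model.  Alkaloid (nicotine-class) content is a
# per-host pass/fail flag, not a mass-balance component.
COMPONENTS = (
    "water",
    "amp",
    "host_soluble_impurity",
    "insoluble_solids",
    "buffer_salts",
    "ethanol",
)

_REL_TOL = 1e-9


@dataclass
class Stream:
    """A material flow, represented as component masses in kg per batch."""

    components: dict[str, float]
    phase_label: str = ""

    def __post_init__(self) -> None:
        for name, mass in self.components.items():
            if mass < 0:
                raise FlowsheetValidationError(
                    f"component {name!r} has negative mass {mass!r}"
                )

    @property
    def total_mass(self) -> float:
        return float(sum(self.components.values()))

    def mass(self, component: str) -> float:
        return float(self.components.get(component, 0.0))

    def fraction(self, component: str) -> float:
        """Mass fraction of *component* in the stream (0 if the stream is empty)."""
        total = self.total_mass
        return self.mass(component) / total if total > 0 else 0.0

    def scaled(self, factor: float) -> "Stream":
        if factor < 0:
            raise FlowsheetValidationError(f"scale factor must be >= 0, got {factor}")
        return Stream(
            {k: v * factor for k, v in self.components.items()},
            phase_label=self.phase_label,
        )

    def plus(self, other: "Stream", phase_label: str | None = None) -> "Stream":
        merged = dict(self.components)
        for k, v in other.components.items():
            merged[k] = merged.get(k, 0.0) + v
        return Stream(merged, phase_label=phase_label or self.phase_label)

    def to_dict(self) -> dict:
        return {
            "phase_label": self.phase_label,
            "total_mass_kg": self.total_mass,
            "components_kg": dict(self.components),
        }


@dataclass(frozen=True)
class AddedInput:
    """A process input added during a stage (e.g. extraction buffer).

    ``ratio`` is kg added per kg of the basis quantity; ``basis`` is either
    the name of a component of the incoming stream or ``"input_total"``.
    ``composition`` gives the mass fractions of the added material and must
    sum to 1.
    """

    name: str
    ratio: float
    basis: str
    composition: Mapping[str, float]

    def validate(self, input_stream: Stream) -> None:
        if self.ratio < 0:
            raise FlowsheetValidationError(
                f"added input {self.name!r}: ratio must be >= 0, got {self.ratio}"
            )
        comp_sum = sum(self.composition.values())
        if abs(comp_sum - 1.0) > 1e-6:
            raise FlowsheetValidationError(
                f"added input {self.name!r}: composition sums to {comp_sum}, not 1"
            )
        if self.basis != "input_total" and self.basis not in input_stream.components:
            raise ConfigurationError(
                f"added input {self.name!r}: unknown basis component {self.basis!r}"
            )

    def amount(self, input_stream: Stream) -> float:
        basis_mass = (
            input_stream.total_mass
            if self.basis == "input_total"
            else input_stream.mass(self.basis)
        )
        return self.ratio * basis_mass

    def as_stream(self, input_stream: Stream) -> Stream:
        total = self.amount(input_stream)
        return Stream(
            {k: total * frac for k, frac in self.composition.items()},
            phase_label=self.name,
        )


@dataclass(frozen=True)
class UnitOpSpec:
    """One processing step: added inputs plus per-component product transfers.

    ``product_transfer`` maps component name to the fraction of the combined
    (input + additions) mass of that component carried into the product
    stream; components not named transfer 0.  ``sizing_basis`` tags whether
    the equipment behind the step is sized by stream volume or by product
    mass, which the economics module uses when resizing.
    """

    name: str
    product_transfer: Mapping[str, float]
    added_inputs: Sequence[AddedInput] = ()
    sizing_basis: str = "volume"  # "volume" | "product_mass"

    def validate(self) -> None:
        for comp, frac in self.product_transfer.items():
            if not 0.0 <= frac <= 1.0:
                raise FlowsheetValidationError(
                    f"op {self.name!r}: transfer fraction for {comp!r} is "
                    f"{frac}, outside [0, 1]"
                )
        if self.sizing_basis not in ("volume", "product_mass"):
            raise ConfigurationError(
                f"op {self.name!r}: unknown sizing_basis {self.sizing_basis!r}"
            )


@dataclass
class StageRecord:
    """Bookkeeping for one executed stage of a batch."""

    op_name: str
    input_stream: Stream
    additions: dict[str, float]
    product_stream: Stream
    waste_stream: Stream
    amp_recovery_this_stage: float

    def to_dict(self) -> dict:
        return {
            "op": self.op_name,
            "input": self.input_stream.to_dict(),
            "additions_kg": dict(self.additions),
            "product": self.product_stream.to_dict(),
            "waste": self.waste_stream.to_dict(),
            "amp_recovery": self.amp_recovery_this_stage,
        }


def propagate(op: UnitOpSpec, input_stream: Stream) -> StageRecord:
    """Run one unit operation on *input_stream* and return its stage record.

    The combined stream (input plus all added inputs) is split component-wise
    between product and waste according to ``op.product_transfer``; mass is
    conserved exactly by construction.
    """
    op.validate()
    combined = input_stream
    additions: dict[str, float] = {}
    for added in op.added_inputs:
        added.validate(input_stream)
        additions[added.name] = added.amount(input_stream)
        combined = combined.plus(added.as_stream(input_stream))

    product: dict[str, float] = {}
    waste: dict[str, float] = {}
    for comp, mass in combined.components.items():
        frac = op.product_transfer.get(comp, 0.0)
        product[comp] = mass * frac
        waste[comp] = mass * (1.0 - frac)

    amp_in = combined.mass("amp")
    amp_out = product.get("amp", 0.0)
    recovery = amp_out / amp_in if amp_in > 0 else 1.0

    return StageRecord(
        op_name=op.name,
        input_stream=input_stream,
        additions=additions,
        product_stream=Stream(product, phase_label=f"{op.name} product"),
        waste_stream=Stream(waste, phase_label=f"{op.name} waste"),
        amp_recovery_this_stage=recovery,
    )


def run_chain(ops: Sequence[UnitOpSpec], input_stream: Stream) -> list[StageRecord]:
    """Propagate a batch through an ordered chain of unit operations."""
    if not ops:
        raise FlowsheetValidationError("cannot run an empty unit-operation chain")
    records: list[StageRecord] = []
    stream = input_stream
    for op in ops:
        record = propagate(op, stream)
        records.append(record)
        stream = record.product_stream
    return records


def cumulative_recovery(records: Iterable[StageRecord]) -> float:
    rec = 1.0
    for record in records:
        rec *= record.amp_recovery_this_stage
    return rec


def chain_amp_recovery(ops: Sequence[UnitOpSpec]) -> float:
    """Overall AMP recovery implied by a chain's transfer coefficients alone."""
    rec = 1.0
    for op in ops:
        rec *= op.product_transfer.get("amp", 0.0)
    return rec


def stage_table(records: Sequence[StageRecord]) -> pd.DataFrame:
    """Tabular batch report: one row per stage (mass, %AMP, %impurity, recovery)."""
    rows = []
    for record in records:
        product = record.product_stream
        rows.append(
            {
                "stage": record.op_name,
                "product_mass_kg": product.total_mass,
                "amp_pct": 100.0 * product.fraction("amp"),
                "host_impurity_pct": 100.0 * product.fraction("host_soluble_impurity"),
                "stage_amp_recovery": record.amp_recovery_this_stage,
            }
        )
    return pd.DataFrame(rows)
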