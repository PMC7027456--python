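"""Report writers: scenario summary, stage table, ledger breakdown, manifest.

All reports are emitted in both JSON and aligned plain text; currency is
reported in USD with explicit unit strings ("$/g", "$ million",
"$ million/year") while internal computation stays in raw dollars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import PhytoTeaError
from .flowsheet import stage_table
from .pipeline import ScenarioResult

_SECTIONS = ("upstream", "downstream")


@dataclass
class RunManifest:
    scenario: str
    config_checksum: str
    package_version: str
    timestamp: str
    output_files: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "config_checksum": self.config_checksum,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
            "output_files": self.output_files,
            "notes": self.notes,
        }


def summary_frame(result: ScenarioResult) -> pd.DataFrame:
    """Scenario summary laid out like the published comparison table."""
    report = result.cost_report
    rows = []
    for section in _SECTIONS:
        rows.append(
            {
                "parameter": "CAPEX",
                "unit": "$ million",
                "section": section,
                "value": report.capex_by_section.get(section, 0.0) / 1e6,
            }
        )
    rows.append(
        {"parameter": "CAPEX", "unit": "$ million", "section": "total",
         "value": report.capex_total / 1e6}
    )
    for section in _SECTIONS:
        rows.append(
            {
                "parameter": "OPEX",
                "unit": "$ million/year",
                "section": section,
                "value": report.opex_by_section.get(section, 0.0) / 1e6,
            }
        )
    rows.append(
        {"parameter": "OPEX", "unit": "$ million/year", "section": "total",
         "value": report.aoc / 1e6}
    )
    for section in _SECTIONS:
        rows.append(
            {
                "parameter": "COGS",
                "unit": "$/g AMP",
                "section": section,
                "value": report.cogs_split.get(section, 0.0),
            }
        )
    rows.append(
        {"parameter": "COGS", "unit": "$/g AMP", "section": "total",
         "value": report.cogs_per_g}
    )
    return pd.DataFrame(rows)


def _round3(value: float) -> float:
    """Round to 3 significant figures for the text summary."""
    return float(f"{value:.3g}")


def write_reports(result: ScenarioResult, outdir: str | Path) -> RunManifest:
    """Write all scenario reports to *outdir* and return the run manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PhytoTeaError(f"cannot create output directory {outdir}: {exc}") from exc

    import hashlib

    manifest = RunManifest(
        scenario=result.config.name,
        config_checksum=hashlib.sha256(result.config.to_yaml().encode()).hexdigest(),
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        manifest.output_files.append(name)

    summary = summary_frame(result)
    summary_json = {
        f"{row.parameter}_{row.section}": _round3(row.value)
        for row in summary.itertuples()
    }
    summary_json["unit_CAPEX"] = "$ million"
    summary_json["unit_OPEX"] = "$ million/year"
    summary_json["unit_COGS"] = "$/g AMP"
    emit("summary.json", json.dumps(summary_json, indent=2))
    pretty = summary.assign(value=summary["value"].map(_round3))
    emit("summary.txt", pretty.to_string(index=False) + "\n")

    if result.stage_records:
        stages = stage_table(result.stage_records)
        emit("stages.csv", stages.to_csv(index=False))
        emit("stages.txt", stages.to_string(index=False) + "\n")
        emit(
            "stages.json",
            json.dumps([r.to_dict() for r in result.stage_records], indent=2),
        )
    else:
        manifest.notes.append("stage table omitted: no stage records")

    ledger = result.cost_report.ledger_frame()
    emit("ledger.csv", ledger.to_csv(index=False))
    emit("ledger.txt", ledger.to_string(index=False) + "\n")

    emit(
        "costs.json",
        json.dumps(result.cost_report.to_dict(), indent=2),
    )
    emit("schedule.json", json.dumps(result.schedule.to_dict(), indent=2))
    emit("upstream_plan.json", json.dumps(result.plan.to_dict(), indent=2))
    emit("quality.json", json.dumps(result.quality.to_dict(), indent=2))

    emit("manifest.json", json.dumps(manifest.to_dict(), indent=2))
    return manifest
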