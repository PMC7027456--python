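# phytomfg-tea

Techno-economic model of a plant-based manufacturing facility for
antimicrobial proteins (AMPs) used as food-safety processing aids.

Bacteriophage endolysins and bacteriocins (colicins, salmocins) can protect
food against major pathogens, but fermentation-based production is too
expensive for the cost-constrained food industry. Whole plants — the plant
itself is the bioreactor — can express these proteins at g/kg fresh-weight
levels. This package models such a facility end to end and asks the
deciding question: **what does a gram of AMP cost to make, and what drives
that cost?**

It is aimed at bioprocess engineers and techno-economic analysts who want a
scriptable, testable model rather than a proprietary simulator file: every
coefficient lives in a human-readable YAML scenario config, and every
result is recomputed from those configs at run time.

## Model

For a facility meeting demand *D* (kg AMP/yr) in *N* batches with host
expression level *E* (g AMP/kg FW) and overall downstream recovery *y*:

```
FW/batch   = D / y / (E/1000) / N
COGS ($/g) = AOC / (1000·D),        AOC = Σ ledger items ($/yr)
CAPEX      = Σ ref_cost·(size/ref_size)^0.6 · installation factor
stagger    = operating days / N;  concurrent batches = ⌈upstream cycle / stagger⌉
```

Batches propagate through a component-mass flowsheet (extraction →
microfiltration/ultrafiltration at 20× concentration → cation-exchange
capture → diafiltration, factor 3 → spray drying) in which each unit
operation is a set of per-component transfer fractions plus buffer
additions; mass is conserved exactly at every stage. Downstream recovery
*y* is the product of the stage AMP transfers. Three calibrated scenarios
ship with the package: indoor *Nicotiana benthamiana* (base case, with
nicotine-clearance chromatography), indoor nicotine-free spinach (no
chromatography), and outdoor field-grown *N. tabacum* (seasonal campaign).
See `docs/methods.md` for the calibration and its assumptions.

## Worked example

```python
import phytomfg_tea as pt

result = pt.run_scenario("base")          # 500 kg/yr, 1 g/kg FW, 91 batches
print(pt.stage_table(result.stage_records).to_string(index=False))
report = result.cost_report
print(f"COGS  ${report.cogs_per_g:.2f}/g "
      f"(up ${report.cogs_split['upstream']:.2f} / "
      f"down ${report.cogs_split['downstream']:.2f})")
print(f"CAPEX ${report.capex_total/1e6:.1f}M, "
      f"inventory {result.schedule.plant_inventory/1e6:.1f}M plants")
```

prints

```
                      stage  product_mass_kg   amp_pct  host_impurity_pct  stage_amp_recovery
                 extraction     11200.000001  0.080000           0.610000            0.941176
clarification_concentration       476.000000  1.410000           0.830000            0.749062
            cation_exchange       236.000000  2.480000           0.220000            0.872042
              diafiltration       230.000000  2.388915           0.210000            0.938782
                  spray_dry         9.060000 60.645756           5.331126            1.000000
COGS  $6.88/g (up $4.02 / down $2.86)
CAPEX $50.1M, inventory 14.6M plants
```

Reading: each 9,520 kg fresh-weight batch carries 9.52 kg AMP; the
11,200 kg screw-press extract is clarified and concentrated to 476 kg,
captured and eluted at 236 kg, buffer-exchanged to 230 kg and spray-dried
into 9.06 kg of powder containing 5.49 kg AMP (60.6% by mass, 92%
protein-basis purity, 42% overall loss). The annual operating cost of
$3.44M over 500 kg/yr gives a $6.88/g cost of goods sold; the soilless
plant substrate alone is 41% of it, which is why the sensitivity tools
focus there:

```bash
phytomfg-tea run --scenario base --outdir out/          # full report set
phytomfg-tea scan-expression --outdir out/              # COGS vs 0.5–5 g/kg
phytomfg-tea scan-production --outdir out/              # COGS vs 100–1,000 kg/yr
phytomfg-tea sensitivity --item "soilless plant substrate" --outdir out/
phytomfg-tea scenario spinach --outdir out/spinach/
phytomfg-tea cost-of-use --cogs 6.88 --juncture meat_product --outdir out/
phytomfg-tea emit-config base --outdir configs/         # YAML + manifest
```

Library equivalents: `pt.expression_scan`, `pt.production_scan`,
`pt.price_sensitivity`, `pt.cost_of_use`, `pt.substrate_reuse_counterfactual`,
`pt.perturb_config` / `pt.validate_consistency`.

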