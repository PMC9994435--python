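# campusfp

Integrated environmental footprint accounting for campuses and other
institutions. `campusfp` computes **greenhouse-gas (GHG), reactive-nitrogen
(N), phosphorus (P) and water (W) footprints from one shared activity
ledger**, projects a business-as-usual (BAU) future, composes
sustainability-action-plan strategies (fuel switches, efficiency gains,
renewable offsets, food substitutions, …) as declarative scenario
transformations, and converts GHG and N releases into monetary damage costs.

It is aimed at sustainability offices and researchers who track more than one
footprint indicator at once and want to see the synergies and tradeoffs of a
planned strategy across all of them, instead of optimizing one footprint while
silently inflating another ("pollution swapping").

## The model

Every footprint is a linear form over the activity ledger
(records of *category, item, quantity, unit, year*):

```
F = Σ_records Σ_forms  quantity × EF(category, item, form)
```

where `EF` is the emission factor for that activity and pollutant form.
For the GHG footprint, CH₄ and N₂O masses are converted to CO₂ equivalents
with 100-year global warming potentials (AR5 defaults: CH₄ 28, N₂O 265)
before summation; totals are metric tons CO₂e (MTCDE). The N footprint sums
NOₓ-N, N₂O-N and "other" (virtual) N in metric tons N; the P footprint (kg P)
draws only on food, fertilizer and wastewater (combustion P is negligible);
the W footprint sums blue, green and direct water in m³ (with a gallon
rendering).

BAU projection multiplies each category by a growth driver (population,
gross square footage, or food demand). Action-plan strategies transform the
ledger and/or factor tables and compose sequentially in catalog order; food
substitutions conserve total food mass so meal counts stay constant.

Damage costs are linear in releases: GHG damages are the total times a social
cost of carbon (default $30/t CO₂e); N damages are $/kg N by pollutant form,
release medium and impacted sector (human health, agriculture, ecosystems,
climate — including a negative aerosol-cooling climate term). Avoided NOₓ
health costs of a scenario follow

```
savings = (NOx_BAU − NOx_scenario) × $damage per ton NOx
```

separately for the ozone and PM₂.₅ pathways.

## Worked example

```python
import campusfp as c

bundle = c.generate_campus_ledger(seed=42)      # synthetic mid-size campus
fp = c.compute_integrated(bundle.ledger, bundle.tables)
print(f"GHG {fp.ghg_total:,.0f} t CO2e | N {fp.n_total:.1f} t | "
      f"P {fp.p_total:,.0f} kg | W {fp.w_total:,.0f} m3")

port = c.run_portfolio(
    bundle.ledger, bundle.drivers, bundle.catalog,
    {"all strategies": [s.id for s in bundle.catalog]},
    bundle.tables,
)
print(port[["scenario", "ghg_pct", "n_pct", "p_pct", "w_pct"]].round(1))
```

prints

```
GHG 175,180 t CO2e | N 202.0 t | P 12,582 kg | W 17,910,498 m3
         scenario  ghg_pct  n_pct  p_pct  w_pct
0   2016 baseline      NaN    NaN    NaN    NaN
1        2025 BAU      0.0    0.0    0.0    0.0
2  all strategies    -38.0  -39.2  -17.2  -25.7
```

The first line is the 2016 synthetic baseline; the `_pct` columns are signed
percent changes of each footprint relative to the 2025 business-as-usual
projection (reductions are negative), here with the full 29-strategy catalog
applied.

A CLI mirrors the library: `campusfp synth`, `footprint`, `project`,
`scenario`, `damage`, `report` (see `campusfp --help`). `report` writes CSV
and JSON tables plus stacked-bar figures with percent-change annotations.

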