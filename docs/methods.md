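# Methods

## Accounting model

All four footprints are computed from a single activity ledger so they can be
compared directly. A ledger is a list of records *(category, item, quantity,
unit, year)* over a controlled vocabulary of ten categories: purchased
electricity, stationary fuels, direct transportation, commuting, food,
fertilizer, animals, refrigerants/chemicals, wastewater, direct water.
Quantities are nonnegative; units must resolve in the package's dimensional
registry (mass, energy, volume, distance, count), and record quantities are
converted into each factor's `per_unit` before multiplication, so a ledger in
kWh works against factors quoted per MWh.

Each footprint total is

    F = Σ_records Σ_forms quantity × EF(category, item, form)

with exact lookups on *(category, item, pollutant form)*. A missing factor
contributes zero and logs a warning rather than raising, because each
footprint intentionally covers only a subset of sectors (e.g. phosphorus
excludes fossil combustion entirely; the engine additionally restricts P to
food, fertilizer and wastewater). Totals are accumulated with `math.fsum`;
per-category and per-form breakdowns always sum to the total (checked at
1e-9 relative in the tests, typically exact to ~1e-15).

Normalized units: GHG in metric tons CO₂e (CH₄ and N₂O converted through
100-year GWPs taken from the factor table; shipped defaults are AR5 values
CH₄ = 28, N₂O = 265 and are configuration, not constants, with provenance
recorded), N in metric tons N, P in kg P, W in m³ internally with a gallon
rendering (1 m³ = 264.172 gal). Refrigerants are ledgered directly in CO₂e
(`refrigerant_CO2e` form). Commuting and direct transportation are distinct
categories.

## Projection

Business-as-usual projection multiplies each record by the growth driver
assigned to its category. The default mapping: food → food demand; purchased
electricity, stationary fuels, refrigerants, direct water → gross square
footage; commuting, direct transportation, wastewater → population;
fertilizer and animals → identity. The mapping is configuration (YAML) so an
institution can override it. Because the engine is linear, projection
commutes with footprint computation and with ledger concatenation, and
composing projections multiplies drivers elementwise — these identities are
property-tested.

## Scenario engine

A strategy is declarative: `{id, name, kind, params, in_nap, in_ghgap}` with
nine kinds. Quantity transformations: `efficiency`, `behavior_reduction` and
`fleet_improvement` multiply target quantities by (1 − fraction);
`food_waste_reduction` by (1 − fraction × avoidable_share); a
`renewable_offset` subtracts a fixed generation amount from purchased
electricity, floored at zero; a `fuel_switch` moves a fraction of one fuel to
another on an energy-content basis (via the unit registry when both fuels are
ledgered in energy units, else via a configurable MJ-per-unit map), so
delivered heat is preserved. Factor transformations: `grid_factor_change` and
`sourcing_factor_change` scale the relevant emission factors instead of the
ledger. `food_substitution` moves a fraction of one or more source items'
mass onto target items by normalized weights; total ledgered food mass is
conserved to keep meal counts constant (an invariant tested across random
parameters).

Composition is sequential in catalog id order, each fraction interpreted
against the running ledger. Overlapping strategies (two acting on beef, say)
are therefore well defined and order-stamped in the output; strategies on
disjoint (category, item) sets commute exactly. No strategy may produce a
negative quantity — results clip at zero with a warning. Strategies that
reference an item absent from the ledger are logged no-ops, since plans are
written against the whole campus while an analysis ledger may cover a subset.

The built-in catalog has 29 strategies mirroring the structure of a
university GHG action plan (rows 1–16, in both plans) and nitrogen action
plan (rows 17–29, food-focused, N plan only). Rows whose percentages appear
in the plans themselves (full coal-to-gas fuel switch; 15 % vegetarian meal
replacement; 20 % and 10 % beef-to-chicken) carry those numbers; all other
numeric parameters (efficiency percentages, solar MWh, small food-shift
fractions) are synthetic defaults flagged `SD1-derived placeholder` in their
params, chosen once as plausible plan magnitudes and exposed through the
catalog YAML for override.

## Damage costs

GHG: total × social cost of carbon. SCC defaults to $30 per t CO₂e, an
intermediate value within the commonly quoted $14–$74 (global) and $1–$7
(national) ranges; it is a parameter. N: each flux (form, medium) is charged
every $/kg entry for that flux across the four impact sectors; sector
rollups, including the negative aerosol-cooling climate term, sum to the
total. Virtual food-chain N is apportioned into dissolved N (0.55), NH₃
(0.30), NOₓ (0.05) and N₂O (0.10) — a documented placeholder scheme,
configuration not fact — and hydrologic N is split 0.5/0.3/0.2 among surface
water, groundwater and coastal systems, likewise a config parameter. Because
the N footprint does not attribute forms per record, the release-vector
builder applies the footprint-wide form shares within each category; this is
an approximation that an itemized ledger-level attribution would refine. All
unit costs in the default damage table are synthetic order-of-magnitude
placeholders with provenance strings; any real valuation must override them
from CSV. Dollar amounts convert between currency years through an annual
CPI series (U.S. CPI-U averages shipped for 2008–2020); internal arithmetic
is full precision and only rendering rounds to whole dollars. Avoided NOₓ
health costs use `(NOx_BAU − NOx_scenario) × $/ton`, per pathway (ozone,
PM₂.₅); the default per-ton figures ($5 000 and $8 500 per t NOₓ-N) are
placeholders of the same kind. No damage costs exist for P and W.

## Synthetic campus generator

`generate_campus_ledger(seed, scale)` emulates the structure of a mid-size
university's annual ledger: all ten categories populated; food items
including beef, chicken, pork, dairy, eggs and vegetarian staples; per-kg GHG
and N factors strictly ordered beef > chicken > plant staples; the food
category at least half of the N footprint; magnitudes of order 1e5 t CO₂e and
1e2 t N. Base quantities are fixed and jittered ±5 % by a seeded generator
(algorithm id recorded in bundle metadata), so bundles are bit-reproducible
per seed while factor orderings hold for every seed. Growth drivers default
to population ×1.12, gross square footage ×1.20, food ×1.18 for a nine-year
horizon — plausible institutional growth, stated once as the generator's
standing conditions.

What the generator does *not* emulate: real ledgers have hundreds of food
line items, month-level granularity, metering gaps and unit heterogeneity
within a category; its factor values are representative magnitudes, not any
published inventory. Passing tests therefore demonstrate the correctness of
the accounting, projection, composition and valuation machinery — linearity,
conservation, commutation, oracle equivalence — not agreement with any
particular institution's published totals, which require that institution's
own activity and factor tables (ingestible via `load_supplementary_tables`).

## Numerical choices and edge cases

- Totals via `fsum`; comparisons in tests at 1e-12 (oracle equivalence) and
  1e-9 (algebraic properties).
- Percent change is `(comparison − baseline)/baseline × 100` and raises on a
  zero baseline; portfolio tables report 0 for a zero-baseline footprint row
  rather than NaN only when baseline and comparison are both zero.
- Empty ledgers yield exactly zero totals and empty breakdowns; `scale=0`
  generates a structurally complete but zero-quantity campus.
- Factor tables reject duplicate (category, item, form) keys at validation,
  not at load, so a report can list every problem at once.
- CSV is comma-separated UTF-8 with "." decimals and required headers;
  ledgers are single-year snapshots (multi-year series are lists of ledgers).

## Problem sizes

The randomized suites use ledgers of up to 200 records (100 ledgers for
oracle equivalence, ≥1000 property cases for engine algebra, 200 random
food substitutions) — sizes chosen to exercise repeated (category, item)
keys and every factor row while keeping the whole suite to a few seconds.

## Known limitations

- No uncertainty propagation on emission factors (point estimates only).
- No cost-of-implementation modeling for strategies; damage costs are
  avoided-damage estimates, not net savings.
- Linear dose–response everywhere; no nonlinear or threshold damages.
- Grey water (dilution requirement) is out of scope; only blue, green and
  direct water are accounted.
- The per-category N form split in the damage pipeline uses footprint-wide
  shares (see above).
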