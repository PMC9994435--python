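"""Action-plan strategies as declarative transformations of a scenario state.

A strategy is the unit of a sustainability action plan: a fuel switch, an
efficiency gain, a renewable offset, a food substitution, and so on.  Each
strategy transforms a scenario state (an activity ledger plus the current
factor tables) into a new state; plans are evaluated by composing their
strategies sequentially in catalog id order, each fraction interpreted
against the running ledger.

Food substitutions conserve total ledgered food mass so the number of meals
stays constant while their composition changes.  No strategy may drive a
quantity negative; results are clipped at zero with a warning.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import units
from .data_model import (
    ActivityLedger,
    ActivityRecord,
    Category,
    FactorTable,
    Footprint,
    GrowthDrivers,
)
from .engine import compute_integrated, percent_change
from .projection import project_bau

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyKind",
    "Strategy",
    "ScenarioState",
    "build_strategy_catalog",
    "default_catalog",
    "save_catalog",
    "apply_strategy",
    "compose_strategies",
    "run_portfolio",
]


class StrategyKind(str, enum.Enum):
    FUEL_SWITCH = "fuel_switch"
    EFFICIENCY = "efficiency"
    GRID_FACTOR_CHANGE = "grid_factor_change"
    RENEWABLE_OFFSET = "renewable_offset"
    FOOD_SUBSTITUTION = "food_substitution"
    FOOD_WASTE_REDUCTION = "food_waste_reduction"
    SOURCING_FACTOR_CHANGE = "sourcing_factor_change"
    FLEET_IMPROVEMENT = "fleet_improvement"
    BEHAVIOR_REDUCTION = "behavior_reduction"


@dataclass(frozen=True)
class Strategy:
    """One action-plan strategy with kind-specific parameters.

    ``in_nap`` / ``in_ghgap`` flag membership in the nitrogen and greenhouse
    gas action plans respectively.
    """

    id: int
    name: str
    kind: StrategyKind
    params: dict = field(default_factory=dict)
    in_nap: bool = True
    in_ghgap: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.kind, StrategyKind):
            object.__setattr__(self, "kind", StrategyKind(self.kind))
        frac = self.params.get("fraction")
        if frac is not None and not (0.0 <= float(frac) <= 1.0):
            raise ValueError(
                f"strategy {self.id} ({self.name}): fraction {frac} not in [0, 1]"
            )
        to_items = self.params.get("to_items")
        if to_items:
            s = sum(float(w) for w in to_items.values())
            if not math.isclose(s, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"strategy {self.id}: substitution weights sum to {s}, not 1"
                )


@dataclass
class ScenarioState:
    """Running state of a scenario: ledger, factor tables, applied strategies."""

    ledger: ActivityLedger
    tables: dict[Footprint, FactorTable]
    applied: list[int] = field(default_factory=list)

    def copy(self) -> "ScenarioState":
        return ScenarioState(
            ledger=ActivityLedger(
                records=list(self.ledger.records),
                label=self.ledger.label,
                year=self.ledger.year,
            ),
            tables=dict(self.tables),
            applied=list(self.applied),
        )


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

_MEATS = ["beef", "chicken", "pork"]
_PLANT_WEIGHTS = {"beans": 0.4, "grains": 0.3, "vegetables": 0.3}

# Default 29-strategy catalog mirroring the two campus action plans.
# Rows 1, 17, 22 and 24 carry the percentages stated in the plans themselves
# (full coal-to-gas switch, 15% vegetarian replacement, 20% and 10% beef-to-
# chicken); the remaining numeric parameters are synthetic defaults standing
# in for plan-internal figures and are flagged as such.
_DEFAULT_ROWS: list[dict] = [
    dict(id=1, name="Fuel optimization", kind="fuel_switch",
         params=dict(category="stationary_fuels", from_item="coal",
                     to_item="natural_gas", fraction=1.0)),
    dict(id=2, name="Chilled water plant efficiency improvements", kind="efficiency",
         params=dict(category="purchased_electricity", fraction=0.04,
                     provenance="SD1-derived placeholder")),
    dict(id=3, name="Heat plant efficiency improvements", kind="efficiency",
         params=dict(category="stationary_fuels", fraction=0.05,
                     provenance="SD1-derived placeholder")),
    dict(id=4, name="Distribution efficiency / low-temperature hot water",
         kind="efficiency",
         params=dict(category="stationary_fuels", fraction=0.05,
                     provenance="SD1-derived placeholder")),
    dict(id=5, name="Grid electricity carbon-intensity improvements",
         kind="grid_factor_change",
         params=dict(category="purchased_electricity", multiplier=0.85,
                     footprints=["GHG", "N"],
                     provenance="SD1-derived placeholder")),
    dict(id=6, name="On-grounds solar", kind="renewable_offset",
         params=dict(amount=6000.0, unit="MWh", item="grid_electricity",
                     provenance="SD1-derived placeholder")),
    dict(id=7, name="Off-grounds utility-scale solar (site 1)",
         kind="renewable_offset",
         params=dict(amount=15000.0, unit="MWh", item="grid_electricity",
                     provenance="SD1-derived placeholder")),
    dict(id=8, name="Off-grounds utility-scale solar (site 2)",
         kind="renewable_offset",
         params=dict(amount=15000.0, unit="MWh", item="grid_electricity",
                     provenance="SD1-derived placeholder")),
    dict(id=9, name="Additional off-grounds utility-scale solar",
         kind="renewable_offset",
         params=dict(amount=30000.0, unit="MWh", item="grid_electricity",
                     provenance="SD1-derived placeholder")),
    dict(id=10, name="Existing building improvements", kind="efficiency",
         params=dict(category="purchased_electricity", fraction=0.06,
                     provenance="SD1-derived placeholder")),
    dict(id=11, name="Green building standards", kind="efficiency",
         params=dict(category="purchased_electricity", fraction=0.03,
                     provenance="SD1-derived placeholder")),
    dict(id=12, name="Green labs", kind="efficiency",
         params=dict(category="purchased_electricity", fraction=0.02,
                     provenance="SD1-derived placeholder")),
    dict(id=13, name="Gasoline fleet improvements", kind="fleet_improvement",
         params=dict(category="direct_transportation", items=["gasoline_miles"],
                     fraction=0.10, provenance="SD1-derived placeholder")),
    dict(id=14, name="Diesel fleet improvements", kind="fleet_improvement",
         params=dict(category="direct_transportation", items=["diesel_miles"],
                     fraction=0.10, provenance="SD1-derived placeholder")),
    dict(id=15, name="Outreach and engagement", kind="behavior_reduction",
         params=dict(category="purchased_electricity", fraction=0.02,
                     provenance="SD1-derived placeholder")),
    dict(id=16, name="Green IT", kind="behavior_reduction",
         params=dict(category="purchased_electricity", fraction=0.02,
                     provenance="SD1-derived placeholder")),
    dict(id=17, name="15% vegetarian meal replacement", kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.15,
                     to_items=dict(_PLANT_WEIGHTS))),
    dict(id=18, name="Meat-focused cafe becomes plant forward",
         kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.02,
                     to_items=dict(_PLANT_WEIGHTS),
                     provenance="SD1-derived placeholder")),
    dict(id=19, name="Plant-forward retail dining", kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.02,
                     to_items=dict(_PLANT_WEIGHTS),
                     provenance="SD1-derived placeholder")),
    dict(id=20, name="Plant-forward theme meals (3 per month)",
         kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.01,
                     to_items=dict(_PLANT_WEIGHTS),
                     provenance="SD1-derived placeholder")),
    dict(id=21, name="Plant-forward Fridays in residential dining",
         kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.03,
                     to_items=dict(_PLANT_WEIGHTS),
                     provenance="SD1-derived placeholder")),
    dict(id=22, name="20% beef replaced with chicken", kind="food_substitution",
         params=dict(from_item="beef", fraction=0.20,
                     to_items={"chicken": 1.0})),
    dict(id=23, name="Blended burgers in dining halls", kind="food_substitution",
         params=dict(from_item="beef", fraction=0.05,
                     to_items={"vegetables": 1.0},
                     provenance="SD1-derived placeholder")),
    dict(id=24, name="10% health-system beef replaced with chicken",
         kind="food_substitution",
         params=dict(from_item="beef", fraction=0.10,
                     to_items={"chicken": 1.0})),
    dict(id=25, name="15% burgers replaced with plant-based burgers",
         kind="food_substitution",
         params=dict(from_item="beef", fraction=0.05,
                     to_items={"beans": 1.0},
                     provenance="SD1-derived placeholder")),
    dict(id=26, name="Mindful Mondays", kind="food_substitution",
         params=dict(from_items=_MEATS, fraction=0.02,
                     to_items=dict(_PLANT_WEIGHTS),
                     provenance="SD1-derived placeholder")),
    dict(id=27, name="Beef-free station for 6 months", kind="food_substitution",
         params=dict(from_item="beef", fraction=0.05,
                     to_items={"chicken": 0.5, "beans": 0.5},
                     provenance="SD1-derived placeholder")),
    dict(id=28, name="50% avoidable food waste reduced",
         kind="food_waste_reduction",
         params=dict(fraction=0.5, avoidable_share=0.10,
                     provenance="SD1-derived placeholder")),
    dict(id=29, name="50% food is sustainably sourced",
         kind="sourcing_factor_change",
         params=dict(category="food", multiplier=0.95,
                     provenance="SD1-derived placeholder")),
]


def default_catalog() -> list[Strategy]:
    """The built-in 29-strategy catalog.

    Rows 1-16 belong to both action plans; rows 17-29 (food strategies) to
    the nitrogen action plan only.
    """
    out = []
    for row in _DEFAULT_ROWS:
        out.append(
            Strategy(
                id=row["id"],
                name=row["name"],
                kind=StrategyKind(row["kind"]),
                params=dict(row["params"]),
                in_nap=True,
                in_ghgap=row["id"] <= 16,
            )
        )
    return out


def build_strategy_catalog(config: str | Path | None = None) -> list[Strategy]:
    """Load a strategy catalog from YAML, or return the built-in defaults.

    The YAML is a list of ``{id, name, kind, params, in_nap, in_ghgap}``
    entries.  Malformed entries raise with the offending row id.
    """
    if config is None:
        return default_catalog()
    data = yaml.safe_load(Path(config).read_text())
    if data is None:
        return []
    catalog: list[Strategy] = []
    seen_ids: set[int] = set()
    for entry in data:
        try:
            s = Strategy(
                id=int(entry["id"]),
                name=str(entry["name"]),
                kind=StrategyKind(entry["kind"]),
                params=dict(entry.get("params") or {}),
                in_nap=bool(entry.get("in_nap", True)),
                in_ghgap=bool(entry.get("in_ghgap", True)),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(
                f"malformed strategy entry (id={entry.get('id')!r}): {exc}"
            ) from exc
        if s.id in seen_ids:
            raise ValueError(f"duplicate strategy id {s.id} in catalog")
        seen_ids.add(s.id)
        catalog.append(s)
    return catalog


def save_catalog(catalog: list[Strategy], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            [
                {
                    "id": s.id,
                    "name": s.name,
                    "kind": s.kind.value,
                    "params": s.params,
                    "in_nap": s.in_nap,
                    "in_ghgap": s.in_ghgap,
                }
                for s in catalog
            ],
            sort_keys=False,
        )
    )
    return path


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------


def _find(records: list[ActivityRecord], category: Category, item: str) -> list[int]:
    return [
        i
        for i, r in enumerate(records)
        if r.category is category and r.item == item
    ]


def _clip(value: float, context: str) -> float:
    if value < 0:
        logger.warning("%s: quantity clipped at 0 (was %g)", context, value)
        return 0.0
    return value


def _scale_records(
    records: list[ActivityRecord],
    category: Category,
    items: list[str] | None,
    multiplier: float,
) -> list[ActivityRecord]:
    out = []
    for r in records:
        if r.category is category and (items is None or r.item in items):
            r = replace(r, quantity=r.quantity * multiplier)
        out.append(r)
    return out


def _apply_fuel_switch(state: ScenarioState, s: Strategy) -> None:
    p = s.params
    category = Category(p.get("category", "stationary_fuels"))
    fraction = float(p["fraction"])
    records = state.ledger.records
    from_idx = _find(records, category, p["from_item"])
    if not from_idx:
        logger.warning(
            "strategy %d (%s): item %r absent from ledger; no-op",
            s.id, s.name, p["from_item"],
        )
        return
    energy_content: dict = p.get("energy_content") or {}

    def to_energy(qty: float, unit: str, item: str) -> float:
        if item in energy_content:
            return qty * float(energy_content[item])  # MJ per native unit
        return units.convert(qty, unit, "MJ")

    def from_energy(mj: float, unit: str, item: str) -> float:
        if item in energy_content:
            return mj / float(energy_content[item])
        return units.convert(mj, "MJ", unit)

    moved_mj = 0.0
    for i in from_idx:
        r = records[i]
        moved = r.quantity * fraction
        moved_mj += to_energy(moved, r.unit, r.item)
        records[i] = replace(r, quantity=_clip(r.quantity - moved, s.name))

    to_idx = _find(records, category, p["to_item"])
    if to_idx:
        r = records[to_idx[0]]
        add = from_energy(moved_mj, r.unit, p["to_item"])
        records[to_idx[0]] = replace(r, quantity=r.quantity + add)
    else:
        # new fuel enters the ledger in MJ unless an energy-content entry
        # defines its native unit implicitly
        records.append(
            ActivityRecord(
                category=category,
                item=p["to_item"],
                quantity=moved_mj if p["to_item"] not in energy_content
                else moved_mj / float(energy_content[p["to_item"]]),
                unit="MJ" if p["to_item"] not in energy_content else p.get(
                    "to_unit", "kg"
                ),
                year=state.ledger.year,
            )
        )


def _apply_quantity_reduction(state: ScenarioState, s: Strategy) -> None:
    """efficiency, behavior_reduction, fleet_improvement, food_waste_reduction."""
    p = s.params
    fraction = float(p["fraction"])
    if s.kind is StrategyKind.FOOD_WASTE_REDUCTION:
        category = Category(p.get("category", "food"))
        items = p.get("items")
        effective = fraction * float(p.get("avoidable_share", 1.0))
    else:
        category = Category(p["category"])
        items = p.get("items")
        effective = fraction
    matched = any(
        r.category is category and (items is None or r.item in items)
        for r in state.ledger.records
    )
    if not matched:
        logger.warning("strategy %d (%s): no matching records; no-op", s.id, s.name)
        return
    state.ledger.records[:] = _scale_records(
        state.ledger.records, category, items, 1.0 - effective
    )


def _apply_factor_change(state: ScenarioState, s: Strategy) -> None:
    """grid_factor_change / sourcing_factor_change: scale emission factors."""
    p = s.params
    category = Category(p["category"])
    items = p.get("items")
    multiplier = float(p["multiplier"])
    footprints = [Footprint(f) for f in p.get("footprints", [f.value for f in Footprint])]
    touched = False
    for fp in footprints:
        table = state.tables[fp]
        new_factors = []
        for f in table.factors:
            if f.category is category and (items is None or f.item in items):
                f = replace(f, value=f.value * multiplier)
                touched = True
            new_factors.append(f)
        state.tables[fp] = FactorTable(
            table.footprint, new_factors, dict(table.gwp), table.provenance
        )
    if not touched:
        logger.warning("strategy %d (%s): no matching factors; no-op", s.id, s.name)


def _apply_renewable_offset(state: ScenarioState, s: Strategy) -> None:
    p = s.params
    category = Category(p.get("category", "purchased_electricity"))
    item = p.get("item")
    records = state.ledger.records
    idx = [
        i
        for i, r in enumerate(records)
        if r.category is category and (item is None or r.item == item)
    ]
    if not idx:
        logger.warning("strategy %d (%s): item %r absent; no-op", s.id, s.name, item)
        return
    remaining = float(p["amount"])
    offset_unit = p.get("unit", "MWh")
    for i in idx:
        if remaining <= 0:
            break
        r = records[i]
        offset_here = units.convert(remaining, offset_unit, r.unit)
        take = min(r.quantity, offset_here)
        records[i] = replace(r, quantity=r.quantity - take)
        remaining -= units.convert(take, r.unit, offset_unit)


def _apply_food_substitution(state: ScenarioState, s: Strategy) -> None:
    p = s.params
    fraction = float(p["fraction"])
    from_items = p.get("from_items") or [p["from_item"]]
    to_items: dict[str, float] = p["to_items"]
    records = state.ledger.records
    moved_kg = 0.0
    any_found = False
    for item in from_items:
        for i in _find(records, Category.FOOD, item):
            any_found = True
            r = records[i]
            moved = r.quantity * fraction
            moved_kg += units.convert(moved, r.unit, "kg")
            records[i] = replace(r, quantity=_clip(r.quantity - moved, s.name))
    if not any_found:
        logger.warning(
            "strategy %d (%s): none of %r in ledger; no-op", s.id, s.name, from_items
        )
        return
    for item, weight in to_items.items():
        share_kg = moved_kg * float(weight)
        idx = _find(records, Category.FOOD, item)
        if idx:
            r = records[idx[0]]
            records[idx[0]] = replace(
                r, quantity=r.quantity + units.convert(share_kg, "kg", r.unit)
            )
        else:
            records.append(
                ActivityRecord(
                    category=Category.FOOD,
                    item=item,
                    quantity=share_kg,
                    unit="kg",
                    year=state.ledger.year,
                )
            )


_APPLIERS = {
    StrategyKind.FUEL_SWITCH: _apply_fuel_switch,
    StrategyKind.EFFICIENCY: _apply_quantity_reduction,
    StrategyKind.BEHAVIOR_REDUCTION: _apply_quantity_reduction,
    StrategyKind.FLEET_IMPROVEMENT: _apply_quantity_reduction,
    StrategyKind.FOOD_WASTE_REDUCTION: _apply_quantity_reduction,
    StrategyKind.GRID_FACTOR_CHANGE: _apply_factor_change,
    StrategyKind.SOURCING_FACTOR_CHANGE: _apply_factor_change,
    StrategyKind.RENEWABLE_OFFSET: _apply_renewable_offset,
    StrategyKind.FOOD_SUBSTITUTION: _apply_food_substitution,
}


def apply_strategy(state: ScenarioState, s: Strategy) -> ScenarioState:
    """Apply one strategy, returning a new scenario state.

    A strategy referencing an absent ledger item is a logged no-op, not an
    error: plans are written against the full campus, while a ledger under
    analysis may cover a subset.
    """
    new = state.copy()
    _APPLIERS[s.kind](new, s)
    new.applied.append(s.id)
    return new


def compose_strategies(
    state: ScenarioState, strategies: list[Strategy]
) -> ScenarioState:
    """Apply strategies sequentially in catalog id order.

    Each strategy's fractions act on the running ledger, so composition is
    well defined even when strategies overlap on the same items.
    """
    ids = [s.id for s in strategies]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate strategy ids in subset: {sorted(ids)}")
    for s in sorted(strategies, key=lambda s: s.id):
        state = apply_strategy(state, s)
    return state


def run_portfolio(
    baseline: ActivityLedger,
    drivers: GrowthDrivers,
    catalog: list[Strategy],
    subsets: dict[str, list[int]],
    tables: dict[Footprint, FactorTable],
    target_year: int = 2025,
) -> pd.DataFrame:
    """Evaluate named strategy subsets against a projected BAU baseline.

    Returns one row per scenario: the original baseline year, the projected
    business-as-usual year, then one row per subset, with the four footprint
    totals and percent change relative to BAU.
    """
    by_id = {s.id: s for s in catalog}
    for name, ids in subsets.items():
        unknown = [i for i in ids if i not in by_id]
        if unknown:
            raise ValueError(f"subset {name!r} references unknown strategy ids {unknown}")

    bau = project_bau(baseline, drivers, target_year)
    base_fp = compute_integrated(baseline, tables)
    bau_fp = compute_integrated(bau, tables)

    rows = []

    def row(name: str, fp, reference=None) -> dict:
        r = {
            "scenario": name,
            "ghg_t": fp.ghg_total,
            "n_t": fp.n_total,
            "p_kg": fp.p_total,
            "w_m3": fp.w_total,
        }
        for col, key in (
            ("ghg_pct", "ghg_total"),
            ("n_pct", "n_total"),
            ("p_pct", "p_total"),
            ("w_pct", "w_total"),
        ):
            if reference is None:
                r[col] = float("nan")
            else:
                base = getattr(reference, key)
                r[col] = percent_change(base, getattr(fp, key)) if base != 0 else 0.0
        return r

    rows.append(row(f"{baseline.year} baseline", base_fp))
    rows.append(row(f"{target_year} BAU", bau_fp, bau_fp))
    for name, ids in subsets.items():
        state = ScenarioState(ledger=bau, tables=dict(tables))
        state = compose_strategies(state, [by_id[i] for i in ids])
        fp = compute_integrated(state.ledger, state.tables)
        rows.append(row(name, fp, bau_fp))
    return pd.DataFrame(rows)
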