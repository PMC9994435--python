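"""Business-as-usual projection: scale a ledger with per-category growth drivers.

A future baseline is obtained by multiplying every record's quantity by the
growth driver assigned to its category (population, gross square footage, food
demand, or identity).  Because the footprint engine is linear, this commutes
with footprint computation: projecting then computing equals scaling the
per-category footprint values directly.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .data_model import ActivityLedger, Category, GrowthDrivers

__all__ = ["project_bau", "load_drivers", "save_drivers", "compose_drivers"]


def project_bau(
    ledger: ActivityLedger, drivers: GrowthDrivers, target_year: int
) -> ActivityLedger:
    """Project a ledger to ``target_year`` under business-as-usual growth.

    Every record's quantity is multiplied by the driver assigned to its
    category; the year is set to ``target_year`` and the label suffixed "BAU".
    Raises if any ledger category lacks a driver assignment.
    """
    for cat in {r.category for r in ledger.records}:
        drivers.multiplier_for(cat)  # raises on unmapped category
    records = [
        replace(
            r,
            quantity=r.quantity * drivers.multiplier_for(r.category),
            year=target_year,
        )
        for r in ledger.records
    ]
    label = f"{ledger.label} BAU" if ledger.label else "BAU"
    return ActivityLedger(records=records, label=label, year=target_year)


def compose_drivers(a: GrowthDrivers, b: GrowthDrivers) -> GrowthDrivers:
    """Elementwise product of two driver sets (same category mapping required)."""
    if a.driver_map != b.driver_map:
        raise ValueError("cannot compose drivers with different category mappings")
    return GrowthDrivers(
        population_mult=a.population_mult * b.population_mult,
        gsf_mult=a.gsf_mult * b.gsf_mult,
        food_mult=a.food_mult * b.food_mult,
        driver_map=dict(a.driver_map),
    )


def load_drivers(path: str | Path) -> GrowthDrivers:
    """Read growth drivers from YAML."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return GrowthDrivers(
        population_mult=float(data.get("population_mult", 1.0)),
        gsf_mult=float(data.get("gsf_mult", 1.0)),
        food_mult=float(data.get("food_mult", 1.0)),
        driver_map={
            Category(k): v for k, v in (data.get("driver_map") or {}).items()
        },
    )


def save_drivers(drivers: GrowthDrivers, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {
                "population_mult": drivers.population_mult,
                "gsf_mult": drivers.gsf_mult,
                "food_mult": drivers.food_mult,
                "driver_map": {
                    k.value: v for k, v in sorted(drivers.driver_map.items())
                },
            },
            sort_keys=True,
        )
    )
    return path
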