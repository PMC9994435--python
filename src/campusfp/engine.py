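"""Footprint computation: activity × emission factor, summed with breakdowns.

Each footprint total is a plain linear form in the ledger quantities:
``total = Σ_records Σ_forms quantity × factor(category, item, form)``,
with CH4 and N2O mass converted to CO2 equivalents through the table's
100-year global warming potentials before summation for the GHG footprint.
Phosphorus draws only on food, fertilizer and wastewater; combustion P is
negligible and excluded.  The water footprint is the sum of blue, green and
direct water forms.  A missing factor contributes zero and is logged as a
warning, because each footprint deliberately covers only a subset of sectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import units
from .data_model import (
    OUTPUT_UNIT,
    P_CATEGORIES,
    ActivityLedger,
    Category,
    FactorTable,
    Footprint,
    IntegratedFootprint,
    PollutantForm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FootprintResult",
    "compute_footprint",
    "compute_integrated",
    "percent_change",
    "aggregate_by_category",
    "UndefinedChangeError",
]


class UndefinedChangeError(ZeroDivisionError):
    """Percent change against a zero baseline is undefined."""


@dataclass
class FootprintResult:
    """One footprint's total with per-category and per-form breakdowns."""

    footprint: Footprint
    total: float
    by_category: dict[Category, float] = field(default_factory=dict)
    by_form: dict[PollutantForm, float] = field(default_factory=dict)
    unit: str = ""
    label: str = ""
    year: int = 0


def _gwp_multiplier(table: FactorTable, form: PollutantForm) -> float:
    """CO2-equivalence multiplier for a GHG pollutant form."""
    if form in (PollutantForm.CH4, PollutantForm.N2O):
        try:
            return table.gwp[form]
        except KeyError:
            raise ValueError(
                f"GHG factor table lacks a GWP for {form.value}"
            ) from None
    return 1.0


def compute_footprint(ledger: ActivityLedger, table: FactorTable) -> FootprintResult:
    """Compute one footprint of a ledger against its factor table.

    Factor lookups are exact on (category, item, pollutant_form); the record
    quantity is converted into the factor's ``per_unit`` and the emitted mass
    (or volume) into the footprint's canonical output unit before summation.
    """
    fp = table.footprint
    out_unit = OUTPUT_UNIT[fp]
    lookup: dict[tuple[Category, str], list] = {}
    for f in table.factors:
        lookup.setdefault((f.category, f.item), []).append(f)

    by_category: dict[Category, float] = {}
    by_form: dict[PollutantForm, float] = {}
    contributions: list[float] = []
    warned: set[tuple[Category, str]] = set()

    for rec in ledger.records:
        if fp is Footprint.P and rec.category not in P_CATEGORIES:
            continue
        factors = lookup.get((rec.category, rec.item))
        if not factors:
            if (rec.category, rec.item) not in warned:
                warned.add((rec.category, rec.item))
                logger.warning(
                    "%s footprint: no factor for (%s, %s); contributes zero",
                    fp.value,
                    rec.category.value,
                    rec.item,
                )
            continue
        for f in factors:
            qty = units.convert(rec.quantity, rec.unit, f.per_unit)
            emitted = units.convert(f.value * qty, f.numerator_unit, out_unit)
            if fp is Footprint.GHG:
                emitted *= _gwp_multiplier(table, f.pollutant_form)
            contributions.append(emitted)
            by_category[rec.category] = by_category.get(rec.category, 0.0) + emitted
            by_form[f.pollutant_form] = by_form.get(f.pollutant_form, 0.0) + emitted

    return FootprintResult(
        footprint=fp,
        total=math.fsum(contributions),
        by_category=by_category,
        by_form=by_form,
        unit=out_unit,
        label=ledger.label,
        year=ledger.year,
    )


def compute_integrated(
    ledger: ActivityLedger, tables: dict[Footprint, FactorTable]
) -> IntegratedFootprint:
    """Compute all four footprints from the same ledger.

    ``tables`` must contain exactly one factor table per footprint.
    """
    tables = {Footprint(k): v for k, v in tables.items()}
    missing = [fp.value for fp in Footprint if fp not in tables]
    if missing:
        raise ValueError(f"missing factor tables for footprints: {missing}")
    for fp, table in tables.items():
        if table.footprint != fp:
            raise ValueError(
                f"table registered under {fp.value} is a "
                f"{table.footprint.value} table"
            )
    results = {fp: compute_footprint(ledger, tables[fp]) for fp in Footprint}
    return IntegratedFootprint(
        ghg_total=results[Footprint.GHG].total,
        n_total=results[Footprint.N].total,
        p_total=results[Footprint.P].total,
        w_total=results[Footprint.W].total,
        by_category={fp: results[fp].by_category for fp in Footprint},
        by_form={fp: results[fp].by_form for fp in Footprint},
        label=ledger.label,
        year=ledger.year,
    )


def percent_change(baseline: float, comparison: float) -> float:
    """Signed percent change from ``baseline`` to ``comparison``.

    Reductions are negative, matching the sign convention used when reporting
    scenario impacts against a business-as-usual baseline.
    """
    if baseline == 0:
        raise UndefinedChangeError("percent change from a zero baseline is undefined")
    return (comparison - baseline) / baseline * 100.0


def aggregate_by_category(result: FootprintResult) -> tuple[dict[Category, float], float]:
    """Per-category values over the full vocabulary (absent categories are 0).

    Returns ``(mapping, total)``; the mapping always sums to the total.
    """
    full = {cat: result.by_category.get(cat, 0.0) for cat in Category}
    return full, result.total
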