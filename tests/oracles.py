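"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's engine internals: unit conversions use
a locally defined constants table and footprint totals are accumulated by a
naive record-by-record, factor-by-factor loop.
"""

from __future__ import annotations

# unit -> (dimension, scale to canonical kg / MJ / m3 / km / head)
_TO_CANON = {
    "kg": ("mass", 1.0),
    "g": ("mass", 1e-3),
    "lb": ("mass", 0.45359237),
    "t": ("mass", 1000.0),
    "ton": ("mass", 907.18474),
    "mj": ("energy", 1.0),
    "kwh": ("energy", 3.6),
    "mwh": ("energy", 3600.0),
    "mmbtu": ("energy", 1055.05585262),
    "therm": ("energy", 105.4804),
    "m3": ("volume", 1.0),
    "l": ("volume", 1e-3),
    "gallon": ("volume", 3.785411784e-3),
    "km": ("distance", 1.0),
    "mile": ("distance", 1.609344),
    "head": ("count", 1.0),
}

_OUT_UNIT = {"GHG": "t", "N": "t", "P": "kg", "W": "m3"}
_P_CATS = {"food", "fertilizer", "wastewater"}


def _conv(value: float, from_unit: str, to_unit: str) -> float:
    df, sf = _TO_CANON[from_unit.lower()]
    dt, st = _TO_CANON[to_unit.lower()]
    assert df == dt, f"incompatible units {from_unit} -> {to_unit}"
    return value * sf / st


def naive_footprint_total(ledger, table) -> float:
    """Brute-force multiply-and-sum over every record x factor pair."""
    fp = table.footprint.value
    out_unit = _OUT_UNIT[fp]
    gwp = {k.value: v for k, v in table.gwp.items()}
    total = 0.0
    for rec in ledger.records:
        if fp == "P" and rec.category.value not in _P_CATS:
            continue
        for f in table.factors:
            if f.category != rec.category or f.item != rec.item:
                continue
            qty = _conv(rec.quantity, rec.unit, f.per_unit)
            emitted = _conv(f.value * qty, f.numerator_unit, out_unit)
            if fp == "GHG" and f.pollutant_form.value in ("CH4", "N2O"):
                emitted *= gwp[f.pollutant_form.value]
            total += emitted
    return total


def naive_by_category(ledger, table) -> dict:
    out: dict = {}
    for rec in ledger.records:
        single = type(ledger)(records=[rec], label="", year=ledger.year)
        v = naive_footprint_total(single, table)
        out[rec.category] = out.get(rec.category, 0.0) + v
    return out


def naive_n_damage_total(vector, entries) -> float:
    """Flux-by-flux, entry-by-entry damage cost accumulation."""
    total = 0.0
    for key, mass in vector.items():
        form, medium = key[-2], key[-1]
        for e in entries:
            if e.pollutant_form == form and e.medium == medium:
                total += mass * e.unit_cost
    return total
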