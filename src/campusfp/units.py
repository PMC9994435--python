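"""Minimal dimensional unit registry for activity and factor units.

Every unit belongs to exactly one dimension (mass, energy, volume, distance,
count) and carries a scale to that dimension's canonical SI-ish unit
(kg, MJ, m3, km, head).  Conversion within a dimension is a ratio of scales,
so round trips are exact up to floating point and conversion is associative.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnitError(ValueError):
    """Raised when a unit symbol is unknown or dimensionally incompatible."""


@dataclass(frozen=True)
class _Unit:
    symbol: str
    dimension: str
    to_canonical: float  # multiply to express in the dimension's canonical unit


# canonical units per dimension: mass=kg, energy=MJ, volume=m3, distance=km,
# count=head
_UNITS: dict[str, _Unit] = {}


def _register(symbol: str, dimension: str, scale: float, *aliases: str) -> None:
    unit = _Unit(symbol, dimension, scale)
    for name in (symbol, *aliases):
        _UNITS[name.lower()] = unit


_register("kg", "mass", 1.0)
_register("g", "mass", 1e-3)
_register("lb", "mass", 0.45359237, "lbs", "pound")
_register("t", "mass", 1000.0, "tonne", "metric_ton", "mt")
_register("ton", "mass", 907.18474, "short_ton")  # US short ton

_register("MJ", "energy", 1.0)
_register("kWh", "energy", 3.6)
_register("MWh", "energy", 3600.0)
_register("MMBtu", "energy", 1055.05585262, "mmbtu")
_register("therm", "energy", 105.4804)

_register("m3", "volume", 1.0, "m^3", "m³")
_register("L", "volume", 1e-3, "liter", "litre")
_register("gallon", "volume", 3.785411784e-3, "gal")
_register("kgal", "volume", 3.785411784, "kgallon")

_register("km", "distance", 1.0)
_register("mile", "distance", 1.609344, "mi", "miles")

_register("head", "count", 1.0, "unit", "count", "each")

#: gallons in one cubic metre, for rendering water volumes both ways
GALLONS_PER_M3 = 1.0 / 3.785411784e-3


def resolve(symbol: str) -> tuple[str, float]:
    """Return (dimension, scale-to-canonical) for a unit symbol.

    Raises UnitError for unknown symbols.
    """
    try:
        unit = _UNITS[symbol.strip().lower()]
    except KeyError:
        raise UnitError(f"unknown unit symbol: {symbol!r}") from None
    return unit.dimension, unit.to_canonical


def dimension_of(symbol: str) -> str:
    return resolve(symbol)[0]


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension."""
    dim_from, scale_from = resolve(from_unit)
    dim_to, scale_to = resolve(to_unit)
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return value * (scale_from / scale_to)


def compatible(unit_a: str, unit_b: str) -> bool:
    """True when both symbols resolve to the same dimension."""
    return dimension_of(unit_a) == dimension_of(unit_b)
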