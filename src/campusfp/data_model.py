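"""Shared domain types, category vocabulary, and ledger/factor-table I/O.

The activity ledger is the single source of activity data from which all four
footprints (greenhouse gas, reactive nitrogen, phosphorus, water) are computed.
Factor tables hold per-(category, item, pollutant form) emission factors for
one footprint each, plus the 100-year global warming potentials needed to
express CH4 and N2O in CO2 equivalents.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import units
from .units import UnitError

__all__ = [
    "Category",
    "Footprint",
    "PollutantForm",
    "ActivityRecord",
    "ActivityLedger",
    "EmissionFactor",
    "FactorTable",
    "IntegratedFootprint",
    "GrowthDrivers",
    "VocabularyError",
    "LedgerValidationError",
    "load_ledger",
    "save_ledger",
    "load_factor_table",
    "save_factor_table",
    "validate_factor_table",
    "UnitError",
]


class VocabularyError(ValueError):
    """An activity category outside the controlled vocabulary."""


class LedgerValidationError(ValueError):
    """A ledger row violating an invariant (e.g. negative quantity)."""


class Category(str, enum.Enum):
    """The ten activity categories an institutional ledger may contain."""

    PURCHASED_ELECTRICITY = "purchased_electricity"
    STATIONARY_FUELS = "stationary_fuels"
    DIRECT_TRANSPORTATION = "direct_transportation"
    COMMUTING = "commuting"
    FOOD = "food"
    FERTILIZER = "fertilizer"
    ANIMALS = "animals"
    REFRIGERANTS_CHEMICALS = "refrigerants_chemicals"
    WASTEWATER = "wastewater"
    DIRECT_WATER = "direct_water"


class Footprint(str, enum.Enum):
    GHG = "GHG"  # metric tons CO2-equivalent (MTCDE)
    N = "N"  # metric tons reactive N
    P = "P"  # kg P
    W = "W"  # m3 freshwater (rendered in gallons as well)


class PollutantForm(str, enum.Enum):
    CO2 = "CO2"
    CH4 = "CH4"
    N2O = "N2O"
    REFRIGERANT_CO2E = "refrigerant_CO2e"
    NOX_N = "NOx_N"
    N2O_N = "N2O_N"
    OTHER_N = "other_N"
    P = "P"
    BLUE_WATER = "blue_water"
    GREEN_WATER = "green_water"
    DIRECT_WATER = "direct_water"


#: pollutant forms admissible in a factor table of each footprint
FORMS_BY_FOOTPRINT: dict[Footprint, frozenset[PollutantForm]] = {
    Footprint.GHG: frozenset(
        {
            PollutantForm.CO2,
            PollutantForm.CH4,
            PollutantForm.N2O,
            PollutantForm.REFRIGERANT_CO2E,
        }
    ),
    Footprint.N: frozenset(
        {PollutantForm.NOX_N, PollutantForm.N2O_N, PollutantForm.OTHER_N}
    ),
    Footprint.P: frozenset({PollutantForm.P}),
    Footprint.W: frozenset(
        {
            PollutantForm.BLUE_WATER,
            PollutantForm.GREEN_WATER,
            PollutantForm.DIRECT_WATER,
        }
    ),
}

#: canonical output unit per footprint (totals are reported in these)
OUTPUT_UNIT: dict[Footprint, str] = {
    Footprint.GHG: "t",
    Footprint.N: "t",
    Footprint.P: "kg",
    Footprint.W: "m3",
}

#: footprint sector exclusions: phosphorus draws only on these categories
#: (combustion P is negligible and excluded by construction)
P_CATEGORIES = frozenset(
    {Category.FOOD, Category.FERTILIZER, Category.WASTEWATER}
)


@dataclass(frozen=True)
class ActivityRecord:
    """One ledger row: a quantity of an item consumed in a year."""

    category: Category
    item: str
    quantity: float
    unit: str
    year: int

    def __post_init__(self) -> None:
        if not isinstance(self.category, Category):
            try:
                object.__setattr__(self, "category", Category(self.category))
            except ValueError:
                raise VocabularyError(
                    f"unknown category {self.category!r}; allowed: "
                    f"{sorted(c.value for c in Category)}"
                ) from None
        q = float(self.quantity)
        if not math.isfinite(q) or q < 0:
            raise LedgerValidationError(
                f"quantity must be finite and >= 0, got {self.quantity!r} "
                f"for ({self.category.value}, {self.item})"
            )
        object.__setattr__(self, "quantity", q)
        units.resolve(self.unit)  # raises UnitError if unresolvable


@dataclass
class ActivityLedger:
    """A single-year campus consumption record."""

    records: list[ActivityRecord] = field(default_factory=list)
    label: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.year != self.year:
                raise LedgerValidationError(
                    f"record year {rec.year} != ledger year {self.year}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Ledger as a DataFrame with columns category,item,quantity,unit,year."""
        return pd.DataFrame(
            {
                "category": [r.category.value for r in self.records],
                "item": [r.item for r in self.records],
                "quantity": [r.quantity for r in self.records],
                "unit": [r.unit for r in self.records],
                "year": [r.year for r in self.records],
            }
        )

    def scaled(self, factor: float) -> "ActivityLedger":
        """New ledger with every quantity multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return ActivityLedger(
            records=[replace(r, quantity=r.quantity * factor) for r in self.records],
            label=self.label,
            year=self.year,
        )

    def concat(self, other: "ActivityLedger") -> "ActivityLedger":
        if other.year != self.year:
            raise LedgerValidationError("cannot concatenate ledgers of different years")
        return ActivityLedger(
            records=self.records + other.records,
            label=self.label,
            year=self.year,
        )


@dataclass(frozen=True)
class EmissionFactor:
    """Emission per unit of activity for one (category, item, pollutant form)."""

    footprint: Footprint
    category: Category
    item: str
    pollutant_form: PollutantForm
    value: float  # mass (or volume) of pollutant per `per_unit` of activity
    numerator_unit: str  # unit of the emitted pollutant, e.g. kg
    per_unit: str  # unit of activity the factor is quoted per, e.g. kWh

    def __post_init__(self) -> None:
        if not isinstance(self.footprint, Footprint):
            object.__setattr__(self, "footprint", Footprint(self.footprint))
        if not isinstance(self.category, Category):
            object.__setattr__(self, "category", Category(self.category))
        if not isinstance(self.pollutant_form, PollutantForm):
            object.__setattr__(
                self, "pollutant_form", PollutantForm(self.pollutant_form)
            )
        if not (math.isfinite(self.value) and self.value >= 0):
            raise LedgerValidationError(
                f"factor value must be finite and >= 0, got {self.value!r}"
            )
        units.resolve(self.numerator_unit)
        units.resolve(self.per_unit)

    @property
    def key(self) -> tuple[Category, str, PollutantForm]:
        return (self.category, self.item, self.pollutant_form)


@dataclass
class FactorTable:
    """All emission factors for one footprint, with GWPs and provenance."""

    footprint: Footprint
    factors: list[EmissionFactor] = field(default_factory=list)
    gwp: dict[PollutantForm, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.footprint, Footprint):
            self.footprint = Footprint(self.footprint)
        self.gwp = {
            (PollutantForm(k) if not isinstance(k, PollutantForm) else k): float(v)
            for k, v in self.gwp.items()
        }

    def lookup(self) -> dict[tuple[Category, str, PollutantForm], EmissionFactor]:
        return {f.key: f for f in self.factors}

    def scaled_factor(
        self,
        category: Category,
        item: str,
        pollutant_form: PollutantForm,
        multiplier: float,
    ) -> "FactorTable":
        """Copy of the table with one factor's value scaled by ``multiplier``."""
        out = []
        for f in self.factors:
            if f.key == (category, item, pollutant_form):
                f = replace(f, value=f.value * multiplier)
            out.append(f)
        return FactorTable(self.footprint, out, dict(self.gwp), self.provenance)


@dataclass
class IntegratedFootprint:
    """The four footprint totals with per-category and per-form breakdowns.

    Units: GHG in metric tons CO2e (MTCDE), N in metric tons N, P in kg P,
    W in m3 (use ``w_total_gallons`` for the gallon rendering).
    """

    ghg_total: float
    n_total: float
    p_total: float
    w_total: float
    by_category: dict[Footprint, dict[Category, float]]
    by_form: dict[Footprint, dict[PollutantForm, float]]
    label: str = ""
    year: int = 0

    @property
    def w_total_gallons(self) -> float:
        return self.w_total * units.GALLONS_PER_M3

    def total(self, footprint: Footprint) -> float:
        return {
            Footprint.GHG: self.ghg_total,
            Footprint.N: self.n_total,
            Footprint.P: self.p_total,
            Footprint.W: self.w_total,
        }[footprint]

    def to_dict(self) -> dict:
        """JSON-ready representation."""
        fp_units = {"GHG": "t CO2e", "N": "t N", "P": "kg P", "W": "m3"}
        return {
            "label": self.label,
            "year": self.year,
            "footprints": {
                fp.value: {
                    "total": self.total(fp),
                    "units": fp_units[fp.value],
                    "by_category": {
                        c.value: v for c, v in self.by_category[fp].items()
                    },
                    "by_form": {f.value: v for f, v in self.by_form[fp].items()},
                }
                for fp in Footprint
            },
        }


@dataclass
class GrowthDrivers:
    """Multiplicative growth drivers for business-as-usual projection."""

    population_mult: float = 1.0
    gsf_mult: float = 1.0  # gross square footage
    food_mult: float = 1.0
    driver_map: dict[Category, str] = field(default_factory=dict)

    #: default assignment of categories to named drivers
    DEFAULT_MAP = {
        Category.FOOD: "food_mult",
        Category.PURCHASED_ELECTRICITY: "gsf_mult",
        Category.STATIONARY_FUELS: "gsf_mult",
        Category.REFRIGERANTS_CHEMICALS: "gsf_mult",
        Category.DIRECT_WATER: "gsf_mult",
        Category.COMMUTING: "population_mult",
        Category.DIRECT_TRANSPORTATION: "population_mult",
        Category.WASTEWATER: "population_mult",
        Category.FERTILIZER: "identity",
        Category.ANIMALS: "identity",
    }

    def __post_init__(self) -> None:
        for name in ("population_mult", "gsf_mult", "food_mult"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not self.driver_map:
            self.driver_map = dict(self.DEFAULT_MAP)
        else:
            self.driver_map = {
                (Category(k) if not isinstance(k, Category) else k): v
                for k, v in self.driver_map.items()
            }
        valid = {"population_mult", "gsf_mult", "food_mult", "identity"}
        for cat, drv in self.driver_map.items():
            if drv not in valid:
                raise ValueError(f"unknown driver {drv!r} for category {cat.value}")

    def multiplier_for(self, category: Category) -> float:
        try:
            driver = self.driver_map[category]
        except KeyError:
            raise ValueError(
                f"category {category.value!r} has no growth driver assigned"
            ) from None
        if driver == "identity":
            return 1.0
        return float(getattr(self, driver))


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

LEDGER_COLUMNS = ["category", "item", "quantity", "unit", "year"]
FACTOR_COLUMNS = [
    "footprint",
    "category",
    "item",
    "pollutant_form",
    "value",
    "numerator_unit",
    "per_unit",
]


def load_ledger(path: str | Path, year: int | None = None) -> ActivityLedger:
    """Read an activity ledger CSV (columns category,item,quantity,unit[,year]).

    Rows are validated against the controlled vocabulary, the nonnegativity
    invariant, and the unit registry; the offending row index is named in
    errors.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"item": str, "unit": str, "category": str})
    missing = [c for c in ("category", "item", "quantity", "unit") if c not in df.columns]
    if missing:
        raise LedgerValidationError(f"{path}: missing columns {missing}")
    if "year" not in df.columns:
        if year is None:
            raise LedgerValidationError(f"{path}: no year column and no year given")
        df["year"] = year
    records: list[ActivityRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ActivityRecord(
                    category=row["category"],
                    item=str(row["item"]),
                    quantity=float(row["quantity"]),
                    unit=str(row["unit"]),
                    year=int(row["year"]),
                )
            )
        except (VocabularyError, LedgerValidationError, UnitError) as exc:
            raise type(exc)(f"{path} row {idx}: {exc}") from None
    ledger_year = year if year is not None else (records[0].year if records else 0)
    return ActivityLedger(records=records, label=path.stem, year=ledger_year)


def save_ledger(ledger: ActivityLedger, path: str | Path) -> Path:
    """Write a ledger as RFC-4180 CSV with a deterministic column order."""
    path = Path(path)
    ledger.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def load_factor_table(path: str | Path, footprint: Footprint | str) -> FactorTable:
    """Read a factor CSV plus optional YAML sidecar (``<stem>.meta.yaml``).

    The sidecar carries the GWP block and a provenance string.
    """
    path = Path(path)
    footprint = Footprint(footprint)
    df = pd.read_csv(path, dtype={"item": str})
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise LedgerValidationError(f"{path}: missing columns {missing}")
    factors = [
        EmissionFactor(
            footprint=row["footprint"],
            category=row["category"],
            item=str(row["item"]),
            pollutant_form=row["pollutant_form"],
            value=float(row["value"]),
            numerator_unit=str(row["numerator_unit"]),
            per_unit=str(row["per_unit"]),
        )
        for _, row in df.iterrows()
    ]
    gwp: dict = {}
    provenance = ""
    sidecar = path.with_suffix("").with_suffix(".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        gwp = meta.get("gwp", {})
        provenance = meta.get("provenance", "")
    return FactorTable(footprint=footprint, factors=factors, gwp=gwp, provenance=provenance)


def save_factor_table(table: FactorTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "footprint": [f.footprint.value for f in table.factors],
            "category": [f.category.value for f in table.factors],
            "item": [f.item for f in table.factors],
            "pollutant_form": [f.pollutant_form.value for f in table.factors],
            "value": [f.value for f in table.factors],
            "numerator_unit": [f.numerator_unit for f in table.factors],
            "per_unit": [f.per_unit for f in table.factors],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")
    sidecar = path.with_suffix("").with_suffix(".meta.yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "gwp": {k.value: v for k, v in table.gwp.items()},
                "provenance": table.provenance,
            },
            sort_keys=True,
        )
    )
    return path


def validate_factor_table(table: FactorTable) -> list[str]:
    """Return a list of findings; an empty list means the table is valid.

    Checks duplicate (category, item, form) keys, footprint/form consistency,
    GWP plausibility, and that P factors stay within the phosphorus sectors.
    """
    findings: list[str] = []
    seen: dict[tuple, int] = {}
    allowed = FORMS_BY_FOOTPRINT[table.footprint]
    for f in table.factors:
        seen[f.key] = seen.get(f.key, 0) + 1
        if f.footprint != table.footprint:
            findings.append(
                f"factor {f.key} declares footprint {f.footprint.value}, "
                f"table is {table.footprint.value}"
            )
        if f.pollutant_form not in allowed:
            findings.append(
                f"pollutant form {f.pollutant_form.value} inconsistent with "
                f"{table.footprint.value} footprint for {f.key}"
            )
        if table.footprint is Footprint.P and f.category not in P_CATEGORIES:
            findings.append(
                f"P factor outside phosphorus sectors (food/fertilizer/"
                f"wastewater): {f.key}"
            )
    for key, count in seen.items():
        if count > 1:
            findings.append(f"duplicate factor key {key} ({count} entries)")
    for form, value in table.gwp.items():
        if not value > 1:
            findings.append(f"gwp[{form.value}] must be > 1, got {value}")
    return findings
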