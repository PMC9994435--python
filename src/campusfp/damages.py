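"""Monetary damage costs of GHG and reactive-nitrogen releases.

GHG damages use a social cost of carbon (SCC, $ per metric ton CO2e; $30
default within the commonly quoted $14-$74 global range).  Nitrogen damages
are marginal costs per kg N, keyed by pollutant form (NOx, NH3, N2O, NO3,
dissolved N), release medium (air, land, surface water, groundwater, coastal)
and impacted sector (human health, agriculture, ecosystems, climate), and are
assumed linear in release.  Aerosol cooling by NOx/NHy enters as a negative
unit cost under the climate sector.  All dollar amounts are pegged to a base
currency year through a consumer-price-index series.

The default unit-cost table ships as a clearly-labelled synthetic stand-in
for the regional estimates the method draws on; every entry is overridable
from CSV.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data_model import Category, Footprint, IntegratedFootprint, PollutantForm

logger = logging.getLogger(__name__)

__all__ = [
    "DamageForm",
    "Medium",
    "ImpactSector",
    "DamageCostEntry",
    "DamageCostTable",
    "ApportionmentScheme",
    "CpiSeries",
    "ghg_damage_cost",
    "apportion_virtual_n",
    "n_damage_cost",
    "adjust_for_inflation",
    "nox_health_savings",
    "build_n_release_vector",
    "default_damage_table",
    "default_cpi_series",
    "load_damage_table",
    "save_damage_table",
    "DEFAULT_SCC",
]

#: default social cost of carbon, $ per metric ton CO2e (2016 USD)
DEFAULT_SCC = 30.0

#: default avoided health costs per metric ton NOx-N reduced (2016 USD);
#: synthetic placeholders for regional ozone / PM2.5 precursor estimates
DEFAULT_NOX_COST_OZONE = 5000.0
DEFAULT_NOX_COST_PM25 = 8500.0


class DamageForm(str, enum.Enum):
    NOX_N = "NOx_N"
    NH3_N = "NH3_N"
    N2O_N = "N2O_N"
    NO3_N = "NO3_N"
    DISSOLVED_N = "dissolved_N"
    CO2E = "CO2e"


class Medium(str, enum.Enum):
    AIR = "air"
    LAND = "land"
    SURFACE_WATER = "surface_water"
    GROUNDWATER = "groundwater"
    COASTAL = "coastal"


class ImpactSector(str, enum.Enum):
    HUMAN_HEALTH = "human_health"
    AGRICULTURE = "agriculture"
    ECOSYSTEMS = "ecosystems"
    CLIMATE = "climate"


@dataclass(frozen=True)
class DamageCostEntry:
    """Marginal cost in $ per kg pollutant for one (form, medium, sector)."""

    pollutant_form: DamageForm
    medium: Medium
    impact_sector: ImpactSector
    unit_cost: float  # $/kg, 2016 USD; may be negative for climate only
    currency_year: int = 2016
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.pollutant_form, DamageForm):
            object.__setattr__(self, "pollutant_form", DamageForm(self.pollutant_form))
        if not isinstance(self.medium, Medium):
            object.__setattr__(self, "medium", Medium(self.medium))
        if not isinstance(self.impact_sector, ImpactSector):
            object.__setattr__(self, "impact_sector", ImpactSector(self.impact_sector))
        if self.unit_cost < 0 and self.impact_sector is not ImpactSector.CLIMATE:
            raise ValueError(
                "negative unit costs are permitted only for the climate sector "
                f"(aerosol cooling); got {self.unit_cost} for "
                f"{self.impact_sector.value}"
            )


@dataclass
class DamageCostTable:
    entries: list[DamageCostEntry] = field(default_factory=list)
    currency_year: int = 2016

    def for_flux(self, form: DamageForm, medium: Medium) -> list[DamageCostEntry]:
        return [
            e
            for e in self.entries
            if e.pollutant_form is form and e.medium is medium
        ]


@dataclass
class ApportionmentScheme:
    """Split of virtual food N into dissolved N, NH3, NOx and N2O fractions."""

    fractions: dict[DamageForm, float]

    def __post_init__(self) -> None:
        self.fractions = {
            (DamageForm(k) if not isinstance(k, DamageForm) else k): float(v)
            for k, v in self.fractions.items()
        }
        for form, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {form.value} not in [0, 1]: {frac}")
        total = math.fsum(self.fractions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"apportionment fractions sum to {total}, not 1")


#: default split of virtual food N -- synthetic stand-in for the literature
#: apportionment; most food-chain N is lost to water, the rest volatilizes
DEFAULT_APPORTIONMENT = ApportionmentScheme(
    {
        DamageForm.DISSOLVED_N: 0.55,
        DamageForm.NH3_N: 0.30,
        DamageForm.NOX_N: 0.05,
        DamageForm.N2O_N: 0.10,
    }
)

#: default split of hydrologic N among receiving waters (config, not a claim)
DEFAULT_HYDRO_SPLIT = {
    Medium.SURFACE_WATER: 0.5,
    Medium.GROUNDWATER: 0.3,
    Medium.COASTAL: 0.2,
}


@dataclass
class CpiSeries:
    """Annual consumer-price-index values for inflation pegging."""

    index: dict[int, float]
    base_year: int = 2016

    def __post_init__(self) -> None:
        self.index = {int(k): float(v) for k, v in self.index.items()}
        for year, value in self.index.items():
            if not value > 0:
                raise ValueError(f"CPI index for {year} must be > 0, got {value}")


def default_cpi_series() -> CpiSeries:
    """US city-average CPI-U annual averages (BLS), 2008-2020."""
    return CpiSeries(
        index={
            2008: 215.303,
            2009: 214.537,
            2010: 218.056,
            2011: 224.939,
            2012: 229.594,
            2013: 232.957,
            2014: 236.736,
            2015: 237.017,
            2016: 240.007,
            2017: 245.120,
            2018: 251.107,
            2019: 255.657,
            2020: 258.811,
        },
        base_year=2016,
    )


def default_damage_table() -> DamageCostTable:
    """Synthetic default unit-cost table ($/kg, 2016 USD).

    Magnitudes are order-of-magnitude plausible for a mid-Atlantic watershed
    (air-quality health costs dominate, eutrophication next, aerosol cooling
    a small negative climate term) but are placeholders, not published
    estimates; override from CSV for any real analysis.
    """
    prov = "synthetic default; override with site-specific estimates"
    e = DamageCostEntry
    entries = [
        e(DamageForm.NOX_N, Medium.AIR, ImpactSector.HUMAN_HEALTH, 15.0, 2016, prov),
        e(DamageForm.NOX_N, Medium.AIR, ImpactSector.AGRICULTURE, 2.0, 2016, prov),
        e(DamageForm.NOX_N, Medium.AIR, ImpactSector.ECOSYSTEMS, 2.0, 2016, prov),
        e(DamageForm.NOX_N, Medium.AIR, ImpactSector.CLIMATE, -2.0, 2016, prov),
        e(DamageForm.NH3_N, Medium.AIR, ImpactSector.HUMAN_HEALTH, 10.0, 2016, prov),
        e(DamageForm.NH3_N, Medium.AIR, ImpactSector.ECOSYSTEMS, 2.0, 2016, prov),
        e(DamageForm.NH3_N, Medium.AIR, ImpactSector.CLIMATE, -1.5, 2016, prov),
        e(DamageForm.N2O_N, Medium.AIR, ImpactSector.CLIMATE, 12.0, 2016, prov),
        e(DamageForm.DISSOLVED_N, Medium.SURFACE_WATER, ImpactSector.ECOSYSTEMS, 8.0, 2016, prov),
        e(DamageForm.DISSOLVED_N, Medium.SURFACE_WATER, ImpactSector.HUMAN_HEALTH, 1.0, 2016, prov),
        e(DamageForm.DISSOLVED_N, Medium.SURFACE_WATER, ImpactSector.AGRICULTURE, 0.5, 2016, prov),
        e(DamageForm.DISSOLVED_N, Medium.GROUNDWATER, ImpactSector.HUMAN_HEALTH, 2.0, 2016, prov),
        e(DamageForm.DISSOLVED_N, Medium.COASTAL, ImpactSector.ECOSYSTEMS, 10.0, 2016, prov),
        e(DamageForm.NO3_N, Medium.GROUNDWATER, ImpactSector.HUMAN_HEALTH, 2.0, 2016, prov),
        e(DamageForm.NO3_N, Medium.SURFACE_WATER, ImpactSector.ECOSYSTEMS, 6.0, 2016, prov),
        e(DamageForm.NO3_N, Medium.COASTAL, ImpactSector.ECOSYSTEMS, 8.0, 2016, prov),
        # SCC expressed per kg for completeness: $30/t = $0.03/kg
        e(DamageForm.CO2E, Medium.AIR, ImpactSector.CLIMATE, 0.03, 2016, prov),
    ]
    return DamageCostTable(entries=entries, currency_year=2016)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def ghg_damage_cost(ghg_total: float, scc: float = DEFAULT_SCC) -> float:
    """GHG damage cost: total in metric tons CO2e times the SCC ($/t)."""
    if scc < 0:
        raise ValueError("social cost of carbon must be >= 0")
    return ghg_total * scc


def apportion_virtual_n(
    food_n: float, scheme: ApportionmentScheme = DEFAULT_APPORTIONMENT
) -> dict[DamageForm, float]:
    """Split virtual food-chain N (any mass unit) into release forms.

    The outputs sum to the input exactly up to floating point.
    """
    return {form: food_n * frac for form, frac in scheme.fractions.items()}


@dataclass
class NDamageResult:
    total: float
    by_sector: dict[ImpactSector, float]
    by_category: dict[Category | None, float]


def n_damage_cost(
    n_by_form_medium: dict, table: DamageCostTable
) -> NDamageResult:
    """Cost of a vector of N releases.

    ``n_by_form_medium`` maps ``(form, medium)`` or ``(category, form,
    medium)`` keys to released mass in kg N.  Each flux is charged every
    sector entry present for its (form, medium); fluxes with no table entry
    contribute zero with a warning.  The sector rollup (including negative
    climate terms) sums to the total.
    """
    by_sector = {s: 0.0 for s in ImpactSector}
    by_category: dict[Category | None, float] = {}
    contributions: list[float] = []
    for key, mass_kg in n_by_form_medium.items():
        if len(key) == 3:
            category, form, medium = key
            category = Category(category) if category is not None else None
        else:
            form, medium = key
            category = None
        form = DamageForm(form)
        medium = Medium(medium)
        entries = table.for_flux(form, medium)
        if not entries:
            logger.warning(
                "no damage-cost entry for (%s, %s); contributes $0",
                form.value,
                medium.value,
            )
            continue
        for entry in entries:
            cost = mass_kg * entry.unit_cost
            contributions.append(cost)
            by_sector[entry.impact_sector] += cost
            by_category[category] = by_category.get(category, 0.0) + cost
    return NDamageResult(
        total=math.fsum(contributions),
        by_sector=by_sector,
        by_category=by_category,
    )


def adjust_for_inflation(
    amount: float, from_year: int, to_year: int, cpi: CpiSeries
) -> float:
    """Re-express ``amount`` from one currency year in another via the CPI."""
    for year in (from_year, to_year):
        if year not in cpi.index:
            raise KeyError(f"year {year} not in CPI series")
    return amount * cpi.index[to_year] / cpi.index[from_year]


def nox_health_savings(
    nox_bau: float,
    nox_scenario: float,
    cost_ozone: float,
    cost_pm25: float,
) -> dict[str, float]:
    """Avoided health costs of a NOx emission reduction.

    Savings = (BAU emissions − scenario emissions) × $/ton, separately for
    the ozone and PM2.5 formation pathways; negative if emissions rise.
    """
    for name, v in (("nox_bau", nox_bau), ("nox_scenario", nox_scenario),
                    ("cost_ozone", cost_ozone), ("cost_pm25", cost_pm25)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    delta = nox_bau - nox_scenario
    ozone = delta * cost_ozone
    pm25 = delta * cost_pm25
    return {"ozone_savings": ozone, "pm25_savings": pm25, "total": ozone + pm25}


# ---------------------------------------------------------------------------
# Release-vector construction from an integrated footprint
# ---------------------------------------------------------------------------


def build_n_release_vector(
    integrated: IntegratedFootprint,
    scheme: ApportionmentScheme = DEFAULT_APPORTIONMENT,
    hydro_split: dict[Medium, float] | None = None,
) -> dict[tuple[Category | None, DamageForm, Medium], float]:
    """Map an N footprint's per-category, per-form masses onto release media.

    Combustion NOx-N and N2O-N go to air.  Virtual food N (the food
    category's "other N") is apportioned into dissolved N, NH3, NOx and N2O;
    the dissolved share and all other hydrologic N (wastewater, fertilizer)
    are split among surface water, groundwater and coastal systems.  Masses
    are returned in kg N (the footprint carries metric tons).
    """
    if hydro_split is None:
        hydro_split = dict(DEFAULT_HYDRO_SPLIT)
    total_split = math.fsum(hydro_split.values())
    if not math.isclose(total_split, 1.0, rel_tol=1e-9):
        raise ValueError(f"hydrologic split sums to {total_split}, not 1")

    n_by_cat = integrated.by_category[Footprint.N]
    n_by_form = integrated.by_form[Footprint.N]
    n_total = integrated.n_total

    vector: dict[tuple[Category | None, DamageForm, Medium], float] = {}

    def add(category, form, medium, mass_kg):
        if mass_kg == 0:
            return
        key = (category, form, medium)
        vector[key] = vector.get(key, 0.0) + mass_kg

    # apportion each category's N by the footprint-wide form shares; exact
    # per-category form splits would need per-record attribution
    for category, cat_t in n_by_cat.items():
        if n_total == 0:
            continue
        for form, form_t in n_by_form.items():
            mass_kg = cat_t * (form_t / n_total) * 1000.0
            if form is PollutantForm.NOX_N:
                add(category, DamageForm.NOX_N, Medium.AIR, mass_kg)
            elif form is PollutantForm.N2O_N:
                add(category, DamageForm.N2O_N, Medium.AIR, mass_kg)
            else:  # other_N: virtual or hydrologic
                if category is Category.FOOD:
                    for dform, dmass in apportion_virtual_n(mass_kg, scheme).items():
                        if dform is DamageForm.DISSOLVED_N:
                            for medium, hfrac in hydro_split.items():
                                add(category, dform, medium, dmass * hfrac)
                        else:
                            add(category, dform, Medium.AIR, dmass)
                else:
                    for medium, hfrac in hydro_split.items():
                        add(category, DamageForm.DISSOLVED_N, medium,
                            mass_kg * hfrac)
    return vector


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

DAMAGE_COLUMNS = [
    "pollutant_form",
    "medium",
    "impact_sector",
    "unit_cost",
    "currency_year",
    "provenance",
]


def load_damage_table(path: str | Path) -> DamageCostTable:
    df = pd.read_csv(path)
    missing = [c for c in DAMAGE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    entries = [
        DamageCostEntry(
            pollutant_form=row["pollutant_form"],
            medium=row["medium"],
            impact_sector=row["impact_sector"],
            unit_cost=float(row["unit_cost"]),
            currency_year=int(row.get("currency_year", 2016)),
            provenance=str(row.get("provenance", "")),
        )
        for _, row in df.iterrows()
    ]
    year = entries[0].currency_year if entries else 2016
    return DamageCostTable(entries=entries, currency_year=year)


def save_damage_table(table: DamageCostTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "pollutant_form": [e.pollutant_form.value for e in table.entries],
            "medium": [e.medium.value for e in table.entries],
            "impact_sector": [e.impact_sector.value for e in table.entries],
            "unit_cost": [e.unit_cost for e in table.entries],
            "currency_year": [e.currency_year for e in table.entries],
            "provenance": [e.provenance for e in table.entries],
        }
    ).to_csv(path, index=False, lineterminator="\n")
    return path
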