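"""Portfolio evaluation and human-readable reporting.

``evaluate_portfolio`` is the end-to-end pipeline: project the baseline
ledger to the target year, apply each named strategy subset, and compute the
four footprints plus GHG and N damage costs for every scenario.  CSV/JSON are
the canonical outputs; the stacked-bar figures are a courtesy rendering.
Percent values are displayed to one decimal place but never rounded
internally.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from .damages import (
    DEFAULT_SCC,
    ApportionmentScheme,
    DEFAULT_APPORTIONMENT,
    build_n_release_vector,
    ghg_damage_cost,
    n_damage_cost,
)
from .data_model import Category, Footprint, IntegratedFootprint, PollutantForm
from .engine import compute_integrated, percent_change
from .projection import project_bau
from .scenarios import ScenarioState, compose_strategies
from .synth import CampusBundle

__all__ = ["evaluate_portfolio", "write_report", "nox_tons"]


def nox_tons(integrated: IntegratedFootprint) -> float:
    """NOx-N mass (metric tons) of an integrated footprint."""
    return integrated.by_form[Footprint.N].get(PollutantForm.NOX_N, 0.0)


def evaluate_portfolio(
    bundle: CampusBundle,
    subsets: dict[str, list[int]],
    target_year: int = 2025,
    scc: float = DEFAULT_SCC,
    scheme: ApportionmentScheme = DEFAULT_APPORTIONMENT,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, IntegratedFootprint]]:
    """Footprints and damage costs for baseline, BAU and each strategy subset.

    Returns ``(portfolio, damage, integrated)`` where ``portfolio`` has the
    four totals and percent changes vs BAU, ``damage`` the GHG and N damage
    costs (plus sector columns for N) and their percent changes, and
    ``integrated`` the full breakdowns per scenario row.
    """
    by_id = {s.id: s for s in bundle.catalog}
    for name, ids in subsets.items():
        unknown = [i for i in ids if i not in by_id]
        if unknown:
            raise ValueError(
                f"subset {name!r} references unknown strategy ids {unknown}"
            )

    baseline = bundle.ledger
    bau = project_bau(baseline, bundle.drivers, target_year)
    scenarios: dict[str, IntegratedFootprint] = {
        f"{baseline.year} baseline": compute_integrated(baseline, bundle.tables),
        f"{target_year} BAU": compute_integrated(bau, bundle.tables),
    }
    bau_name = f"{target_year} BAU"
    for name, ids in subsets.items():
        state = ScenarioState(ledger=bau, tables=dict(bundle.tables))
        state = compose_strategies(state, [by_id[i] for i in ids])
        scenarios[name] = compute_integrated(state.ledger, state.tables)

    bau_fp = scenarios[bau_name]
    bau_ghg_cost = ghg_damage_cost(bau_fp.ghg_total, scc)
    bau_n_cost = n_damage_cost(
        build_n_release_vector(bau_fp, scheme), bundle.damage_table
    ).total

    portfolio_rows, damage_rows = [], []
    for name, fp in scenarios.items():
        is_ref = name == f"{baseline.year} baseline"
        row = {
            "scenario": name,
            "ghg_t": fp.ghg_total,
            "n_t": fp.n_total,
            "p_kg": fp.p_total,
            "w_m3": fp.w_total,
        }
        for col, value, base in (
            ("ghg_pct", fp.ghg_total, bau_fp.ghg_total),
            ("n_pct", fp.n_total, bau_fp.n_total),
            ("p_pct", fp.p_total, bau_fp.p_total),
            ("w_pct", fp.w_total, bau_fp.w_total),
        ):
            row[col] = (
                float("nan") if is_ref or base == 0 else percent_change(base, value)
            )
        portfolio_rows.append(row)

        ghg_cost = ghg_damage_cost(fp.ghg_total, scc)
        n_result = n_damage_cost(
            build_n_release_vector(fp, scheme), bundle.damage_table
        )
        drow = {
            "scenario": name,
            "ghg_cost_usd": ghg_cost,
            "n_cost_usd": n_result.total,
            "ghg_cost_pct": float("nan")
            if is_ref or bau_ghg_cost == 0
            else percent_change(bau_ghg_cost, ghg_cost),
            "n_cost_pct": float("nan")
            if is_ref or bau_n_cost == 0
            else percent_change(bau_n_cost, n_result.total),
        }
        for sector, cost in n_result.by_sector.items():
            drow[f"n_{sector.value}_usd"] = cost
        damage_rows.append(drow)

    return pd.DataFrame(portfolio_rows), pd.DataFrame(damage_rows), scenarios


def _annotate_pct(ax, bars, pcts) -> None:
    for bar, pct in zip(bars, pcts):
        if pct == pct:  # not NaN
            ax.annotate(
                f"{pct:.1f}%",
                (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                ha="center",
                va="bottom",
                fontsize=8,
            )


def write_report(
    portfolio: pd.DataFrame,
    damage: pd.DataFrame | None,
    out: str | Path,
    integrated: dict[str, IntegratedFootprint] | None = None,
    inputs: dict | None = None,
) -> Path:
    """Write CSV/JSON tables plus bar figures with percent annotations.

    ``integrated`` enables stacked-by-category footprint bars; ``inputs``
    (name -> file path) is checksummed into ``run_meta.yaml`` so every report
    is traceable to its inputs.
    """
    out = Path(out)
    (out / "figures").mkdir(parents=True, exist_ok=True)

    portfolio.to_csv(out / "results.csv", index=False, lineterminator="\n")
    (out / "results.json").write_text(
        json.dumps(portfolio.to_dict(orient="records"), indent=2,
                   allow_nan=True)
    )
    if damage is not None:
        damage.to_csv(out / "damage.csv", index=False, lineterminator="\n")

    panels = [
        ("ghg_t", "ghg_pct", "GHG (t CO2e)"),
        ("n_t", "n_pct", "N (t)"),
        ("p_kg", "p_pct", "P (kg)"),
        ("w_m3", "w_pct", "W (m3)"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(12, 8))
    names = portfolio["scenario"].tolist()
    for ax, (col, pct_col, title) in zip(axes.flat, panels):
        fp = Footprint(title.split(" ")[0])
        if integrated is not None:
            # stacked by activity category
            bottom = [0.0] * len(names)
            for cat in Category:
                heights = [
                    integrated[n].by_category[fp].get(cat, 0.0) for n in names
                ]
                if any(h > 0 for h in heights):
                    ax.bar(names, heights, bottom=bottom, label=cat.value)
                    bottom = [b + h for b, h in zip(bottom, heights)]
            bars = ax.bar(names, [0] * len(names), bottom=bottom)
            _annotate_pct(ax, bars, portfolio[pct_col].tolist())
        else:
            bars = ax.bar(names, portfolio[col].tolist())
            _annotate_pct(ax, bars, portfolio[pct_col].tolist())
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=30, labelsize=7)
    if integrated is not None:
        axes.flat[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "figures" / "footprints.png", dpi=100)
    plt.close(fig)

    if damage is not None:
        fig, axes = plt.subplots(1, 2, figsize=(12, 4))
        for ax, (col, pct_col, title) in zip(
            axes,
            [
                ("ghg_cost_usd", "ghg_cost_pct", "GHG damage cost ($)"),
                ("n_cost_usd", "n_cost_pct", "N damage cost ($)"),
            ],
        ):
            bars = ax.bar(damage["scenario"], damage[col])
            _annotate_pct(ax, bars, damage[pct_col].tolist())
            ax.set_title(title)
            ax.tick_params(axis="x", rotation=30, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / "figures" / "damage.png", dpi=100)
        plt.close(fig)

    meta: dict = {"inputs": {}}
    for name, path in (inputs or {}).items():
        p = Path(path)
        if p.exists():
            meta["inputs"][name] = {
                "path": str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
    (out / "run_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out
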