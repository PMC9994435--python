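import math

import pytest
from hypothesis import given, settings, strategies as st

from campusfp import units
from campusfp.data_model import (
    ActivityLedger,
    ActivityRecord,
    Category,
    Footprint,
)
from campusfp.engine import compute_integrated
from campusfp.projection import project_bau
from campusfp.scenarios import (
    ScenarioState,
    Strategy,
    StrategyKind,
    apply_strategy,
    build_strategy_catalog,
    compose_strategies,
    default_catalog,
    run_portfolio,
    save_catalog,
)


def food_mass_kg(ledger) -> float:
    return math.fsum(
        units.convert(r.quantity, r.unit, "kg")
        for r in ledger.records
        if r.category is Category.FOOD
    )


def _state(bundle):
    return ScenarioState(ledger=bundle.ledger, tables=dict(bundle.tables))


class TestCatalog:
    def test_default_catalog_has_29_strategies(self):
        assert len(default_catalog()) == 29

    def test_rows_1_to_16_in_both_plans_rest_nap_only(self):
        for s in default_catalog():
            assert s.in_nap
            assert s.in_ghgap == (s.id <= 16)

    def test_yaml_round_trip(self, tmp_path):
        cat = default_catalog()
        path = save_catalog(cat, tmp_path / "catalog.yaml")
        back = build_strategy_catalog(path)
        assert [(s.id, s.name, s.kind, s.in_ghgap) for s in back] == [
            (s.id, s.name, s.kind, s.in_ghgap) for s in cat
        ]

    def test_empty_config_gives_empty_catalog(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        assert build_strategy_catalog(p) == []

    def test_fraction_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            Strategy(1, "bad", StrategyKind.EFFICIENCY,
                     params={"category": "food", "fraction": 1.5})

    def test_substitution_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="weights"):
            Strategy(1, "bad", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "beef", "fraction": 0.2,
                             "to_items": {"chicken": 0.5, "beans": 0.2}})

    def test_duplicate_catalog_id_rejected(self, tmp_path):
        p = tmp_path / "dup.yaml"
        p.write_text(
            "- {id: 1, name: a, kind: efficiency, params: {category: food, fraction: 0.1}}\n"
            "- {id: 1, name: b, kind: efficiency, params: {category: food, fraction: 0.1}}\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_strategy_catalog(p)


class TestApplyStrategy:
    def test_beef_to_chicken_moves_mass_and_conserves_food_total(self, bundle):
        state = _state(bundle)
        before_beef = next(
            r.quantity for r in state.ledger.records if r.item == "beef"
        )
        before_chicken = next(
            r.quantity for r in state.ledger.records if r.item == "chicken"
        )
        s = Strategy(22, "beef to chicken", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "beef", "fraction": 0.2,
                             "to_items": {"chicken": 1.0}})
        new = apply_strategy(state, s)
        after_beef = next(r.quantity for r in new.ledger.records if r.item == "beef")
        after_chicken = next(
            r.quantity for r in new.ledger.records if r.item == "chicken"
        )
        assert after_beef == pytest.approx(0.8 * before_beef, rel=1e-12)
        assert after_chicken == pytest.approx(
            before_chicken + 0.2 * before_beef, rel=1e-12
        )
        assert food_mass_kg(new.ledger) == pytest.approx(
            food_mass_kg(state.ledger), rel=1e-9
        )

    def test_substitution_creates_missing_target_item(self):
        led = ActivityLedger(
            records=[ActivityRecord(Category.FOOD, "beef", 100.0, "t", 2016)],
            year=2016,
        )
        state = ScenarioState(ledger=led, tables={})
        s = Strategy(1, "s", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "beef", "fraction": 0.2,
                             "to_items": {"chicken": 1.0}})
        new = apply_strategy(state, s)
        chicken = [r for r in new.ledger.records if r.item == "chicken"]
        assert len(chicken) == 1
        assert units.convert(chicken[0].quantity, chicken[0].unit, "t") == pytest.approx(
            20.0, rel=1e-12
        )

    @given(frac=st.floats(0.0, 1.0), w=st.floats(0.01, 0.99),
           seed=st.integers(0, 500))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_random_substitutions_conserve_food_mass(self, bundle, frac, w, seed):
        state = _state(bundle)
        s = Strategy(
            90, "rand", StrategyKind.FOOD_SUBSTITUTION,
            params={"from_items": ["beef", "pork"], "fraction": frac,
                    "to_items": {"beans": w, "grains": 1.0 - w}},
        )
        new = apply_strategy(state, s)
        assert food_mass_kg(new.ledger) == pytest.approx(
            food_mass_kg(state.ledger), rel=1e-9
        )

    def test_zero_fraction_is_identity(self, bundle):
        state = _state(bundle)
        for kind, params in [
            (StrategyKind.FOOD_SUBSTITUTION,
             {"from_item": "beef", "fraction": 0.0, "to_items": {"chicken": 1.0}}),
            (StrategyKind.EFFICIENCY,
             {"category": "purchased_electricity", "fraction": 0.0}),
            (StrategyKind.FUEL_SWITCH,
             {"from_item": "coal", "to_item": "natural_gas", "fraction": 0.0}),
        ]:
            new = apply_strategy(state, Strategy(91, "zero", kind, params=params))
            for a, b in zip(state.ledger.records, new.ledger.records):
                assert a.quantity == b.quantity

    def test_full_fuel_switch_zeroes_coal_and_conserves_energy(self, bundle):
        state = _state(bundle)
        coal = next(r for r in state.ledger.records if r.item == "coal")
        gas = next(r for r in state.ledger.records if r.item == "natural_gas")
        s = Strategy(1, "fuel optimization", StrategyKind.FUEL_SWITCH,
                     params={"from_item": "coal", "to_item": "natural_gas",
                             "fraction": 1.0})
        new = apply_strategy(state, s)
        new_coal = next(r for r in new.ledger.records if r.item == "coal")
        new_gas = next(r for r in new.ledger.records if r.item == "natural_gas")
        assert new_coal.quantity == 0.0
        # both ledgered in MMBtu, so delivered energy is conserved exactly
        assert new_gas.quantity == pytest.approx(
            gas.quantity + coal.quantity, rel=1e-12
        )

    def test_absent_item_is_noop_not_error(self, bundle):
        state = _state(bundle)
        s = Strategy(92, "ghost", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "venison", "fraction": 0.5,
                             "to_items": {"beans": 1.0}})
        new = apply_strategy(state, s)
        for a, b in zip(state.ledger.records, new.ledger.records):
            assert a.quantity == b.quantity

    def test_renewable_offset_floors_at_zero(self):
        led = ActivityLedger(
            records=[ActivityRecord(Category.PURCHASED_ELECTRICITY,
                                    "grid_electricity", 1000.0, "kWh", 2016)],
            year=2016,
        )
        state = ScenarioState(ledger=led, tables={})
        s = Strategy(6, "huge solar", StrategyKind.RENEWABLE_OFFSET,
                     params={"amount": 99.0, "unit": "MWh",
                             "item": "grid_electricity"})
        new = apply_strategy(state, s)
        assert new.ledger.records[0].quantity == 0.0

    def test_grid_factor_change_scales_factor_not_ledger(self, bundle):
        state = _state(bundle)
        s = Strategy(5, "grid", StrategyKind.GRID_FACTOR_CHANGE,
                     params={"category": "purchased_electricity",
                             "multiplier": 0.5, "footprints": ["GHG"]})
        new = apply_strategy(state, s)
        for a, b in zip(state.ledger.records, new.ledger.records):
            assert a.quantity == b.quantity
        old_f = [f for f in state.tables[Footprint.GHG].factors
                 if f.category is Category.PURCHASED_ELECTRICITY][0]
        new_f = [f for f in new.tables[Footprint.GHG].factors
                 if f.category is Category.PURCHASED_ELECTRICITY][0]
        assert new_f.value == pytest.approx(0.5 * old_f.value, rel=1e-12)

    def test_applied_list_records_order(self, bundle):
        state = _state(bundle)
        catalog = {s.id: s for s in default_catalog()}
        state = apply_strategy(state, catalog[22])
        state = apply_strategy(state, catalog[1])
        assert state.applied == [22, 1]


class TestCompose:
    def test_empty_subset_is_identity(self, bundle):
        state = _state(bundle)
        new = compose_strategies(state, [])
        for a, b in zip(state.ledger.records, new.ledger.records):
            assert a.quantity == b.quantity

    def test_duplicate_ids_rejected(self, bundle):
        s = default_catalog()[0]
        with pytest.raises(ValueError, match="duplicate"):
            compose_strategies(_state(bundle), [s, s])

    def test_disjoint_category_strategies_commute_exactly(self, bundle):
        elec = Strategy(10, "elec eff", StrategyKind.EFFICIENCY,
                        params={"category": "purchased_electricity",
                                "fraction": 0.25})
        beef = Strategy(22, "beef", StrategyKind.FOOD_SUBSTITUTION,
                        params={"from_item": "beef", "fraction": 0.2,
                                "to_items": {"chicken": 1.0}})
        ab = apply_strategy(apply_strategy(_state(bundle), elec), beef)
        ba = apply_strategy(apply_strategy(_state(bundle), beef), elec)
        qa = sorted((r.category.value, r.item, r.quantity) for r in ab.ledger.records)
        qb = sorted((r.category.value, r.item, r.quantity) for r in ba.ledger.records)
        assert qa == qb

    def test_compose_equals_stepwise_application_in_id_order(self, bundle):
        catalog = default_catalog()
        composed = compose_strategies(_state(bundle), catalog)
        stepped = _state(bundle)
        for s in sorted(catalog, key=lambda s: s.id):
            stepped = apply_strategy(stepped, s)
        assert composed.applied == stepped.applied == sorted(s.id for s in catalog)
        qa = sorted((r.category.value, r.item, r.quantity)
                    for r in composed.ledger.records)
        qb = sorted((r.category.value, r.item, r.quantity)
                    for r in stepped.ledger.records)
        assert qa == qb

    def test_three_strategy_composition_matches_hand_computation(self):
        """Sequential semantics on a tiny ledger, verified by closed form."""
        led = ActivityLedger(
            records=[
                ActivityRecord(Category.FOOD, "beef", 100.0, "kg", 2016),
                ActivityRecord(Category.FOOD, "chicken", 50.0, "kg", 2016),
                ActivityRecord(Category.PURCHASED_ELECTRICITY,
                               "grid_electricity", 1000.0, "kWh", 2016),
            ],
            year=2016,
        )
        strategies = [
            Strategy(1, "eff", StrategyKind.EFFICIENCY,
                     params={"category": "purchased_electricity", "fraction": 0.1}),
            Strategy(2, "sub", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "beef", "fraction": 0.2,
                             "to_items": {"chicken": 1.0}}),
            Strategy(3, "sub2", StrategyKind.FOOD_SUBSTITUTION,
                     params={"from_item": "beef", "fraction": 0.5,
                             "to_items": {"chicken": 1.0}}),
        ]
        state = compose_strategies(
            ScenarioState(ledger=led, tables={}), strategies
        )
        by_item = {r.item: r.quantity for r in state.ledger.records}
        # beef: 100 * 0.8 * 0.5 = 40 ; chicken: 50 + 20 + 40 = 110 ; elec: 900
        assert by_item["beef"] == pytest.approx(40.0, rel=1e-12)
        assert by_item["chicken"] == pytest.approx(110.0, rel=1e-12)
        assert by_item["grid_electricity"] == pytest.approx(900.0, rel=1e-12)

    def test_no_strategy_yields_negative_quantities(self, bundle):
        state = compose_strategies(_state(bundle), default_catalog())
        assert all(r.quantity >= 0 for r in state.ledger.records)

    def test_full_catalog_never_increases_any_footprint(self, bundle):
        """No pollution-swapping: every footprint falls (or holds) vs BAU."""
        bau = project_bau(bundle.ledger, bundle.drivers, 2025)
        state = ScenarioState(ledger=bau, tables=dict(bundle.tables))
        state = compose_strategies(state, default_catalog())
        before = compute_integrated(bau, bundle.tables)
        after = compute_integrated(state.ledger, state.tables)
        for fp in Footprint:
            assert after.total(fp) <= before.total(fp) * (1 + 1e-12)


class TestRunPortfolio:
    def test_no_subsets_gives_two_reference_rows(self, bundle):
        df = run_portfolio(bundle.ledger, bundle.drivers, default_catalog(), {},
                           bundle.tables)
        assert len(df) == 2
        assert df["scenario"].tolist() == ["2016 baseline", "2025 BAU"]

    def test_all_zero_fraction_strategies_give_zero_percent_change(self, bundle):
        catalog = [
            Strategy(i, f"noop{i}", StrategyKind.EFFICIENCY,
                     params={"category": "food", "fraction": 0.0})
            for i in range(1, 4)
        ]
        df = run_portfolio(bundle.ledger, bundle.drivers, catalog,
                           {"noops": [1, 2, 3]}, bundle.tables)
        row = df[df["scenario"] == "noops"].iloc[0]
        for col in ("ghg_pct", "n_pct", "p_pct", "w_pct"):
            assert row[col] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_strategy_id_rejected(self, bundle):
        with pytest.raises(ValueError, match="unknown strategy ids"):
            run_portfolio(bundle.ledger, bundle.drivers, default_catalog(),
                          {"bad": [999]}, bundle.tables)

    def test_portfolio_row_matches_direct_recomputation(self, bundle):
        """Pipeline self-consistency for the beef-to-chicken strategy row."""
        catalog = default_catalog()
        df = run_portfolio(bundle.ledger, bundle.drivers, catalog,
                           {"beef": [22]}, bundle.tables)
        bau = project_bau(bundle.ledger, bundle.drivers, 2025)
        state = ScenarioState(ledger=bau, tables=dict(bundle.tables))
        state = apply_strategy(state, next(s for s in catalog if s.id == 22))
        direct = compute_integrated(state.ledger, state.tables)
        bau_fp = compute_integrated(bau, bundle.tables)
        row = df[df["scenario"] == "beef"].iloc[0]
        assert row["ghg_t"] == pytest.approx(direct.ghg_total, rel=1e-12)
        assert row["n_pct"] == pytest.approx(
            (direct.n_total - bau_fp.n_total) / bau_fp.n_total * 100, rel=1e-9
        )
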