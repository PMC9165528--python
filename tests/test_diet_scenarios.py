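import pytest

import nfootprint as nf
import nfootprint.diet_scenarios as ds
from nfootprint.core_io import CATEGORIES, default_profile
from nfootprint.nue_vnf import NUEComponents, domestic_vnf


class TestNUETransformation:
    def test_thirty_percent_boost(self):
        out = ds.apply_nue_scenario(NUEComponents(0.40, 0.9, 0.85), 1.3)
        assert out.cultivation_nue == pytest.approx(0.52)
        assert out.processing_nue == 0.9 and out.consumer_nue == 0.85

    def test_capped_at_one(self):
        out = ds.apply_nue_scenario(NUEComponents(0.90, 1.0, 1.0), 1.3)
        assert out.cultivation_nue == 1.0

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(Exception):
            ds.apply_nue_scenario(NUEComponents(0.4, 1.0, 1.0), 0.9)

    def test_vnf_shrinks_accordingly(self):
        before = domestic_vnf(NUEComponents(0.4, 1.0, 1.0))
        after = domestic_vnf(ds.apply_nue_scenario(NUEComponents(0.4, 1.0, 1.0), 1.3))
        assert before == pytest.approx(1 / 0.4)
        assert after == pytest.approx(1 / 0.52)


class TestScenarioSpec:
    @pytest.mark.parametrize(
        "name,mult,diet",
        [("BAU", 1.0, False), ("NUE", 1.3, False),
         ("EAT_LANCET", 1.0, True), ("INTEGRATED", 1.3, True)],
    )
    def test_canonical_specs(self, name, mult, diet):
        spec = ds.scenario_spec(name)
        assert spec.nue_multiplier == mult and spec.diet_altered == diet
        assert spec.baseline_year == 2013 and spec.horizon == 2050
        assert spec.protein_anchor == 51.0

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(Exception):
            ds.ScenarioSpec(name="BAU", nue_multiplier=1.3)

    def test_unknown_name_rejected(self):
        with pytest.raises(Exception):
            ds.scenario_spec("WORST_CASE")


class TestDietAlteration:
    def _deltas(self, country, religion, actual_shares):
        profile = default_profile(religion, 1.0)
        actual = ds.DietShares(country, religion, actual_shares)
        return ds.diet_alteration(actual, ds.eat_lancet_target(), profile)

    def test_bangladesh_muslim_cereals(self):
        deltas = self._deltas("Bangladesh", "Muslim", {"cereals": 68.0,
                                                       "other plant products": 10.0})
        assert deltas["cereals"] == pytest.approx(-36.0)

    def test_pakistan_buddhist_cereals(self):
        deltas = self._deltas("Pakistan", "Buddhist", {"cereals": 56.0,
                                                       "other plant products": 33.0})
        assert deltas["cereals"] == pytest.approx(-24.0)

    def test_fixed_point_when_actual_equals_target(self):
        profile = default_profile("Muslim", 1.0)
        target = ds.eat_lancet_target()
        actual = ds.DietShares("India", "Muslim", dict(ds.EAT_LANCET_SHARES))
        deltas = ds.diet_alteration(actual, target, profile)
        assert all(d == 0.0 for d in deltas.values())

    def test_small_gaps_suppressed(self):
        deltas = self._deltas("Bangladesh", "Muslim",
                              {"cereals": 33.0, "starchy roots": 3.5,
                               "fruits": 4.0})
        assert deltas["cereals"] == 0.0
        assert deltas["starchy roots"] == 0.0

    def test_buddhist_never_gains_animal_or_dairy_share(self):
        deltas = self._deltas("Pakistan", "Buddhist",
                              {"cereals": 56.0, "vegetables": 1.0})
        for cat in ("meat and offal", "eggs", "fish and seafood",
                    "milk and dairy products"):
            assert deltas[cat] == 0.0

    def test_animal_categories_never_altered(self):
        deltas = self._deltas("India", "Muslim",
                              {"cereals": 45.0, "meat and offal": 1.0,
                               "eggs": 0.5, "fish and seafood": 1.0,
                               "fruits": 5.0})
        for cat in ("meat and offal", "eggs", "fish and seafood"):
            assert deltas[cat] == 0.0

    def test_dairy_protected_for_hindu_and_muslim_only(self):
        shares = {"cereals": 40.0, "milk and dairy products": 25.0,
                  "fruits": 2.0}
        for rel in ("Muslim", "Hindu"):
            assert self._deltas("Pakistan", rel, shares)[
                "milk and dairy products"] == 0.0
        for rel in ("Christian", "Others"):
            assert self._deltas("Pakistan", rel, shares)[
                "milk and dairy products"] == pytest.approx(-19.0)

    def test_increase_side_conserves_freed_share(self):
        deltas = self._deltas("Nepal", "Muslim",
                              {"cereals": 50.0, "starchy roots": 10.0,
                               "oil crops and pulses": 4.0, "vegetables": 3.0,
                               "fruits": 4.0, "other plant products": 21.0})
        assert sum(deltas.values()) == pytest.approx(0.0, abs=1e-9)

    def test_printed_cereal_cells_for_all_communities(self, table2):
        for (country, religion), cells in table2.items():
            actual = {c: (cell.actual or 0.0) for c, cell in cells.items()}
            profile = default_profile(religion, 1.0)
            shares = {c: v for c, v in actual.items() if profile.permits(c)}
            deltas = ds.diet_alteration(
                ds.DietShares(country, religion, shares),
                ds.eat_lancet_target(), profile,
            )
            assert deltas["cereals"] == pytest.approx(
                cells["cereals"].alteration
            ), (country, religion)


class TestAlteredSupply:
    def _fixture(self):
        items = {
            "cer": nf.FoodItem("cer", "cereal", "cereals"),
            "cer2": nf.FoodItem("cer2", "cereal 2", "cereals"),
            "veg": nf.FoodItem("veg", "veg", "vegetables"),
            "oil": nf.FoodItem("oil", "pulse", "oil crops and pulses"),
            "fru": nf.FoodItem("fru", "fruit", "fruits"),
            "oth": nf.FoodItem("oth", "other", "other plant products"),
        }
        supplies = [
            nf.SupplyRecord("India", 2013, "cer", 30.0),
            nf.SupplyRecord("India", 2013, "cer2", 10.0),
            nf.SupplyRecord("India", 2013, "veg", 5.0),
            nf.SupplyRecord("India", 2013, "oil", 5.0),
            nf.SupplyRecord("India", 2013, "fru", 0.0),
            nf.SupplyRecord("India", 2013, "oth", 0.0),
        ]
        return items, supplies

    def test_zero_alteration_is_identity(self):
        items, supplies = self._fixture()
        out = ds.altered_protein_supply(supplies, items, {}, protein_anchor=None,
                                        anchor_mode="none")
        assert out == supplies

    def test_single_category_scaling_with_anchor_disabled(self):
        items, supplies = self._fixture()
        # cereals hold 80% of 50 g/day; a -40-point delta halves them
        out = ds.altered_protein_supply(
            supplies, items, {"cereals": -40.0}, protein_anchor=None,
            anchor_mode="none",
        )
        by_id = {s.item_id: s.protein_supply for s in out}
        assert by_id["cer"] == pytest.approx(15.0)
        assert by_id["cer2"] == pytest.approx(5.0)
        assert by_id["veg"] == pytest.approx(5.0)
        assert by_id["oil"] == pytest.approx(5.0)

    def test_decrease_categories_land_exactly_on_target_shares(self):
        items, supplies = self._fixture()
        profile = default_profile("Muslim", 1.0)
        shares, _ = ds.protein_shares(supplies, items, profile)
        deltas = ds.diet_alteration(
            ds.DietShares("India", "Muslim", shares), ds.eat_lancet_target(),
            profile, integer_deltas=False,
        )
        out = ds.altered_protein_supply(supplies, items, deltas, profile,
                                        protein_anchor=None, anchor_mode="none")
        new_shares, _ = ds.protein_shares(out, items, profile)
        assert new_shares["cereals"] == pytest.approx(32.0, abs=1e-9)

    def test_anchor_rescales_total_protein(self):
        items, supplies = self._fixture()
        out = ds.altered_protein_supply(supplies, items, {}, protein_anchor=51.0,
                                        anchor_mode="rescale")
        assert sum(s.protein_supply for s in out) == pytest.approx(51.0)

    def test_empty_category_with_items_absorbs_share_evenly(self):
        items, supplies = self._fixture()
        out = ds.altered_protein_supply(supplies, items, {"fruits": 10.0},
                                        protein_anchor=None, anchor_mode="none")
        by_id = {s.item_id: s.protein_supply for s in out}
        assert by_id["fru"] == pytest.approx(5.0)  # 10 points of 50 g/day

    def test_positive_share_without_category_items_is_infeasible(self):
        items, supplies = self._fixture()
        with pytest.raises(ds.InfeasibleAlterationError):
            ds.altered_protein_supply(supplies, items, {"eggs": 5.0},
                                      protein_anchor=None, anchor_mode="none")

    def test_negative_altered_share_is_infeasible(self):
        items, supplies = self._fixture()
        with pytest.raises(ds.InfeasibleAlterationError):
            ds.altered_protein_supply(supplies, items, {"vegetables": -50.0},
                                      protein_anchor=None, anchor_mode="none")


class TestScenarioBuild:
    def _regional(self, results):
        return [r for r in results
                if r.scope == "ISC average" and r.religion == "all"][0]

    def test_bau_freezes_baseline(self, baseline_2013):
        inputs = nf.build_scenario_inputs(ds.scenario_spec("BAU"), baseline_2013)
        assert inputs.components == baseline_2013.components
        for (country, _), recs in inputs.supplies.items():
            assert recs == [s for s in baseline_2013.supplies
                            if s.country == country]
        assert list(inputs.years) == list(range(2014, 2051))

    def test_nue_scenario_lowers_production_footprint(self, baseline_2013):
        bau = nf.scenario_footprint(
            nf.build_scenario_inputs(ds.scenario_spec("BAU"), baseline_2013))
        nue = nf.scenario_footprint(
            nf.build_scenario_inputs(ds.scenario_spec("NUE"), baseline_2013))
        assert self._regional(nue).production_nf < self._regional(bau).production_nf
        # consumption side untouched by efficiency gains
        assert self._regional(nue).consumption_nf == pytest.approx(
            self._regional(bau).consumption_nf)

    def test_integrated_not_above_single_scenarios(self, baseline_2013):
        totals = {}
        for name in ds.SCENARIO_NAMES:
            res = nf.scenario_footprint(
                nf.build_scenario_inputs(ds.scenario_spec(name), baseline_2013))
            totals[name] = self._regional(res).total_nf
        assert totals["INTEGRATED"] <= totals["NUE"] + 1e-9
        assert totals["INTEGRATED"] <= totals["EAT_LANCET"] + 1e-9
        assert totals["NUE"] < totals["BAU"]

    def test_build_is_idempotent(self, baseline_2013):
        spec = ds.scenario_spec("INTEGRATED")
        once = nf.build_scenario_inputs(spec, baseline_2013)
        twice = nf.build_scenario_inputs(spec, once)
        assert once.components == twice.components
        assert once.supplies == twice.supplies

    def test_nue_and_diet_compose_order_independently(self, baseline_2013):
        integrated = nf.build_scenario_inputs(ds.scenario_spec("INTEGRATED"),
                                              baseline_2013)
        a = nf.build_scenario_inputs(
            ds.scenario_spec("EAT_LANCET"),
            nf.build_scenario_inputs(ds.scenario_spec("NUE"), baseline_2013))
        b = nf.build_scenario_inputs(
            ds.scenario_spec("NUE"),
            nf.build_scenario_inputs(ds.scenario_spec("EAT_LANCET"),
                                     baseline_2013))
        assert a.components == b.components == integrated.components
        assert a.supplies == b.supplies == integrated.supplies

    def test_buddhist_supplies_keep_exclusions_after_alteration(
        self, baseline_2013
    ):
        inputs = nf.build_scenario_inputs(ds.scenario_spec("EAT_LANCET"),
                                          baseline_2013)
        items = inputs.items
        for (country, religion), recs in inputs.supplies.items():
            if religion != "Buddhist":
                continue
            for s in recs:
                if items[s.item_id].category in (
                    "meat and offal", "eggs", "fish and seafood",
                    "milk and dairy products",
                ):
                    assert s.protein_supply == 0.0
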