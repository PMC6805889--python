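"""Farm-gate LCA: gas pathways, allocation rules, per-commodity profiles."""

import pytest
from hypothesis import given, settings, strategies as st

from agroshift import lca_engine as lca
from agroshift.lca_engine import (
    EmissionFactorSet,
    EntericParams,
    GwpSet,
    aggregate_gwp,
    allocate_coproducts,
    commodity_emissions,
    enteric_ch4,
    manure_system_expansion,
    soil_n2o,
)
from agroshift.synthetic_data import CONVENTIONAL, ORGANIC


class TestSoilN2O:
    def test_zero_nitrogen_zero_n2o(self):
        assert soil_n2o({"synthetic": 0.0}, 0.3) == 0.0

    def test_direct_pathway_hand_value(self):
        # 100 kg N x EF 0.01 x 44/28 = 1.571 kg N2O
        ef = EmissionFactorSet(ef_direct=0.01, ef_leach=0.0, ef_volat=0.0)
        assert soil_n2o({"synthetic": 100.0}, 0.0, ef) == pytest.approx(1.571, abs=0.001)

    @given(n=st.floats(0, 500), leach=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_n_inputs(self, n, leach):
        one = soil_n2o({"synthetic": n, "manure": n / 2 if n else 0.0}, leach)
        two = soil_n2o({"synthetic": 2 * n, "manure": n}, leach)
        assert two == pytest.approx(2 * one, rel=1e-9, abs=1e-12)

    def test_manure_volatilises_more_than_synthetic(self):
        assert soil_n2o({"manure": 100.0}, 0.3) > soil_n2o({"synthetic": 100.0}, 0.3)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            soil_n2o({"synthetic": -1.0}, 0.3)

    def test_heavy_wet_classes_leach_more(self):
        ef = EmissionFactorSet()
        assert ef.leach_fraction_for("heavy", "very_wet") > ef.leach_fraction_for("medium", "dry")


class TestEntericCh4:
    def test_zero_intake_zero_methane(self):
        assert enteric_ch4(0.0, 0.5) == 0.0

    def test_more_forage_means_more_methane_at_fixed_intake(self):
        assert enteric_ch4(5000.0, 1.0) >= enteric_ch4(5000.0, 0.0)

    def test_linear_in_dry_matter_intake(self):
        p = EntericParams()
        assert enteric_ch4(6000.0, 0.7, 550.0, 6.0, p) == pytest.approx(
            2 * enteric_ch4(3000.0, 0.7, 550.0, 6.0, p)
        )

    def test_forage_share_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            enteric_ch4(1000.0, 1.5)


class TestAllocation:
    def test_single_product_takes_everything(self):
        assert allocate_coproducts(100.0, [(1.0, 5.0)]) == [pytest.approx(100.0)]

    def test_grain_straw_value_split(self):
        shares = allocate_coproducts(100.0, [(1.0, 90.0), (1.0, 10.0)])
        assert shares == [pytest.approx(90.0), pytest.approx(10.0)]

    def test_common_organic_multiplier_cancels(self):
        base = allocate_coproducts(100.0, [(2.0, 30.0), (1.0, 60.0)])
        scaled = allocate_coproducts(
            100.0, [(2.0, 30.0), (1.0, 60.0)], price_multipliers=[1.3, 1.3]
        )
        assert base == pytest.approx(scaled)

    @given(
        burden=st.floats(0, 1e6),
        prices=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_allocated_burdens_conserve_the_total(self, burden, prices):
        shares = allocate_coproducts(burden, [(1.0, p) for p in prices])
        assert sum(shares) == pytest.approx(burden, rel=1e-9, abs=1e-9)

    def test_all_zero_value_is_an_error(self):
        with pytest.raises(ValueError):
            allocate_coproducts(10.0, [(1.0, 0.0)])


class TestSystemExpansion:
    @pytest.mark.parametrize("n, burden, credit", [(0.0, 6.0, 0.0), (100.0, 6.0, 600.0)])
    def test_credit_is_displaced_fertiliser_burden(self, n, burden, credit):
        assert manure_system_expansion(n, burden) == pytest.approx(credit)


class TestGwpAggregation:
    @pytest.mark.parametrize(
        "co2, ch4, n2o, expected",
        [(1, 0, 0, 1.0), (0, 1, 0, 25.0), (0, 0, 1, 298.0)],
    )
    def test_definition(self, co2, ch4, n2o, expected):
        assert aggregate_gwp(co2, ch4, n2o) == pytest.approx(expected)

    @given(
        a=st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)),
        b=st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)),
    )
    @settings(max_examples=50, deadline=None)
    def test_exactly_additive(self, a, b):
        s = tuple(x + y for x, y in zip(a, b))
        assert aggregate_gwp(*s) == pytest.approx(
            aggregate_gwp(*a) + aggregate_gwp(*b), rel=1e-12, abs=1e-9
        )

    def test_horizon_fixed_at_100_years(self):
        with pytest.raises(ValueError):
            GwpSet(horizon=20)


@pytest.fixture(scope="module")
def profiles(toy_economy, toy_solutions):
    return {
        s: commodity_emissions(toy_economy, toy_solutions[s], s)
        for s in (CONVENTIONAL, ORGANIC)
    }


class TestCommodityEmissions:
    def test_profiles_cover_produced_commodities(self, toy_solutions, profiles):
        for system in (CONVENTIONAL, ORGANIC):
            produced = {c for c, t in toy_solutions[system].production.items() if t > 0}
            assert produced <= set(profiles[system])

    def test_co2e_aggregates_components_exactly(self, profiles):
        gwp = GwpSet()
        for system in profiles:
            for p in profiles[system].values():
                assert p.co2e == pytest.approx(
                    p.co2 + gwp.gwp_ch4 * p.ch4 + gwp.gwp_n2o * p.n2o, rel=1e-12
                )

    def test_feed_burden_lands_on_livestock_not_crops(self, toy_economy, toy_solutions):
        # removing the livestock feed-pool allocation must not change crop profiles
        sol = toy_solutions[CONVENTIONAL]
        profiles = commodity_emissions(toy_economy, sol, CONVENTIONAL)
        crop_names = {c.commodity for c in toy_economy.crops_by_use("food")}
        livestock_names = {l.species for l in toy_economy.livestock_activities}
        produced_livestock = {
            s for s in livestock_names if sol.production.get(s, 0) > 0
        }
        assert produced_livestock, "fixture must produce livestock"
        # feed crops never appear as marketed commodities
        feed_names = {c.commodity for c in toy_economy.crop_activities if c.use != "food"}
        assert not feed_names & set(profiles)
        # livestock carry feed burdens: their CO2 intensity exceeds bare housing energy
        for s in produced_livestock:
            ls = next(l for l in toy_economy.livestock_activities if l.species == s)
            heads = sum(
                v for a, v in sol.activity_levels.items()
                if a[0] == "livestock" and a[2] == s
            )
            bare = ls.energy_co2_per_head[CONVENTIONAL] * heads / sol.production[s]
            assert profiles[s].co2 > bare

    def test_national_total_reaggregates_from_per_tonne(self, toy_economy, toy_solutions):
        sol = toy_solutions[ORGANIC]
        profiles = commodity_emissions(toy_economy, sol, ORGANIC)
        total = sum(
            profiles[c].co2e * t for c, t in sol.production.items() if c in profiles
        )
        recomputed = sum(
            p.co2e * sol.production[c] for c, p in profiles.items()
        )
        assert total == pytest.approx(recomputed, rel=1e-12)

    def test_per_tonne_profile_invariant_to_uniform_scaling(self, toy_economy, toy_solutions):
        import copy

        sol = toy_solutions[CONVENTIONAL]
        scaled = copy.deepcopy(sol)
        scaled.activity_levels = {a: 2 * v for a, v in sol.activity_levels.items()}
        scaled.production = {c: 2 * t for c, t in sol.production.items()}
        base = commodity_emissions(toy_economy, sol, CONVENTIONAL)
        doubled = commodity_emissions(toy_economy, scaled, CONVENTIONAL)
        for c in base:
            assert doubled[c].co2e == pytest.approx(base[c].co2e, rel=1e-9)

    def test_crop_with_no_inputs_has_zero_profile(self):
        from agroshift.land_use_optimizer import build_lp, solve_lp
        from agroshift.synthetic_data import generate_known_optimum_case

        # the single-crop archetype has zero N offtake and no energy coefficients
        economy, system, _ = generate_known_optimum_case("single_crop")
        sol = solve_lp(build_lp(economy, system))
        profiles = commodity_emissions(economy, sol, system)
        p = profiles["wheat"]
        assert (p.co2, p.ch4, p.n2o, p.co2e) == (0.0, 0.0, 0.0, 0.0)

    def test_requires_optimal_solution(self, toy_economy, toy_solutions):
        import copy

        bad = copy.deepcopy(toy_solutions[CONVENTIONAL])
        bad.status = "infeasible"
        with pytest.raises(ValueError):
            commodity_emissions(toy_economy, bad, CONVENTIONAL)
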