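"""Land-use LP: construction, solver correctness, aggregation."""

import copy

import numpy as np
import pytest

from agroshift import land_use_optimizer as luo
from agroshift.land_use_optimizer import (
    ConfigurationError, LandUseSolution, build_lp, national_production, solve_lp,
)
from agroshift.synthetic_data import (
    CONVENTIONAL, ORGANIC, SYSTEMS, CropActivity, Economy, EconomyParams,
    FarmType, LandClass, generate_known_optimum_case,
)


def one_class_economy(crops, area=100.0, n_deposition=0.0):
    lc = LandClass("medium", "medium", area)
    econ = Economy(
        land_classes=[lc],
        farm_types=[FarmType("specialist cropping", {lc.key: area})],
        crop_activities=crops,
        livestock_activities=[],
        demand={},
        params=EconomyParams(
            n_deposition=n_deposition,
            rotation_max_share={g: 1.0 for g in ("cereals", "roots", "legumes", "forage")},
        ),
    )
    econ.validate()
    return econ


def simple_crop(name, y, me, n_off=0.0, n_fix=0.0, baseline=float("inf"), group="cereals"):
    return CropActivity(
        commodity=name,
        yield_by_class={s: {"medium:medium": y} for s in SYSTEMS},
        me_coefficient=me, n_offtake=n_off, n_fixation=n_fix,
        rotation_group=group, baseline_supply=baseline, is_legume=n_fix > 0,
    )


def brute_force_optimum(crops, area, n_deposition=0.0, step=0.01):
    """Enumeration oracle for one land class and <= 3 crops: grid over areas,
    keep the best feasible (land + nitrogen) objective."""
    grids = [np.arange(0.0, area + step / 2, step) for _ in crops[:-1]]
    me_per_ha = [c.yield_by_class[ORGANIC]["medium:medium"] * c.me_coefficient for c in crops]
    n_per_ha = [
        c.n_offtake * c.yield_by_class[ORGANIC]["medium:medium"] - c.n_fixation
        for c in crops
    ]
    best = 0.0
    if len(crops) == 1:
        allocs = [[a] for a in np.arange(0.0, area + step / 2, step)]
    else:
        mesh = np.meshgrid(*grids, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        last = area - flat.sum(axis=1)
        keep = last >= -1e-12
        allocs = np.column_stack([flat[keep], np.maximum(last[keep], 0.0)])
    allocs = np.asarray(allocs)
    n_balance = allocs @ np.asarray(n_per_ha)
    feasible = n_balance <= n_deposition * area + 1e-9
    if feasible.any():
        objective = allocs @ np.asarray(me_per_ha)
        best = float(objective[feasible].max())
    return best


class TestBuildLp:
    def test_single_crop_single_class_shape(self):
        econ = one_class_economy([simple_crop("wheat", 8.0, 13.0)])
        problem = build_lp(econ, CONVENTIONAL)
        crop_cols = [a for a in problem.activities if a[0] == "crop"]
        assert len(crop_cols) == 1
        land_rows = [i for i, r in enumerate(problem.row_ids) if r.startswith("land:")]
        assert len(land_rows) == 1
        assert problem.endowments[land_rows[0]] == pytest.approx(100.0)

    def test_cap_row_rhs_is_150_percent_of_baseline(self):
        econ = one_class_economy([simple_crop("wheat", 8.0, 13.0, baseline=1000.0)])
        problem = build_lp(econ, CONVENTIONAL)
        cap = problem.row_ids.index("cap:wheat")
        assert problem.endowments[cap] == pytest.approx(1500.0)

    def test_missing_yield_coefficient_names_the_pair(self):
        bad = CropActivity(
            commodity="wheat",
            yield_by_class={s: {} for s in SYSTEMS},
            me_coefficient=10.0, n_offtake=10.0,
        )
        econ = one_class_economy([bad])
        with pytest.raises(ConfigurationError, match="wheat.*medium:medium"):
            build_lp(econ, CONVENTIONAL)

    def test_organic_cereal_only_cannot_produce_without_legume(self):
        # with no N source the N balance forces the cereal area to zero
        cereal = simple_crop("wheat", 8.0, 13.0, n_off=20.0)
        econ = one_class_economy([cereal], n_deposition=0.0)
        sol = solve_lp(build_lp(econ, ORGANIC))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        # enabling a legume unlocks production
        econ2 = one_class_economy(
            [cereal, simple_crop("beans", 5.0, 12.0, n_fix=200.0, group="legumes")],
            n_deposition=0.0,
        )
        assert solve_lp(build_lp(econ2, ORGANIC)).objective > 0

    def test_conventional_fertiliser_relaxes_the_n_row(self):
        cereal = simple_crop("wheat", 8.0, 13.0, n_off=20.0)
        econ = one_class_economy([cereal], n_deposition=0.0)
        sol = solve_lp(build_lp(econ, CONVENTIONAL))
        assert sol.objective == pytest.approx(100.0 * 8.0 * 13.0, rel=1e-9)


class TestSolveLp:
    @pytest.mark.parametrize("kind", ["single_crop", "two_crop_cap", "n_limited"])
    def test_archetype_objectives(self, kind):
        economy, system, expected = generate_known_optimum_case(kind)
        sol = solve_lp(build_lp(economy, system))
        assert sol.objective == pytest.approx(expected.objective, rel=1e-6)

    def test_capped_commodity_sits_exactly_at_cap(self):
        economy, system, expected = generate_known_optimum_case("two_crop_cap")
        sol = solve_lp(build_lp(economy, system))
        assert sol.production["potatoes"] == pytest.approx(1.5 * 400.0, rel=1e-9)
        assert "cap:potatoes" in sol.binding_constraints

    def test_objective_consistent_with_activity_levels(self, toy_solutions):
        for system, sol in toy_solutions.items():
            total = sum(
                sol.production[c] for c in sol.production
            )
            assert sol.status == "optimal"
            assert sol.objective >= 0 and np.isfinite(sol.objective)
            assert total >= 0

    def test_matches_brute_force_enumeration(self):
        # <= 3 activities, one class: exhaustive grid search oracle
        crops = [
            simple_crop("wheat", 8.0, 13.0, n_off=20.0),
            simple_crop("beans", 5.0, 12.0, n_fix=200.0, group="legumes"),
        ]
        econ = one_class_economy(crops, area=100.0, n_deposition=0.0)
        sol = solve_lp(build_lp(econ, ORGANIC))
        oracle = brute_force_optimum(crops, 100.0, n_deposition=0.0, step=0.01)
        # tolerance: objective change over one grid step
        step_increment = 0.01 * max(
            c.yield_by_class[ORGANIC]["medium:medium"] * c.me_coefficient for c in crops
        )
        assert abs(sol.objective - oracle) <= step_increment

    def test_three_activity_brute_force(self):
        crops = [
            simple_crop("wheat", 8.0, 13.0, n_off=20.0),
            simple_crop("oats", 6.0, 11.0, n_off=15.0),
            simple_crop("beans", 5.0, 12.0, n_fix=200.0, group="legumes"),
        ]
        econ = one_class_economy(crops, area=10.0, n_deposition=5.0)
        sol = solve_lp(build_lp(econ, ORGANIC))
        oracle = brute_force_optimum(crops, 10.0, n_deposition=5.0, step=0.05)
        step_increment = 0.05 * max(
            c.yield_by_class[ORGANIC]["medium:medium"] * c.me_coefficient for c in crops
        )
        assert abs(sol.objective - oracle) <= step_increment

    def test_relaxing_any_endowment_never_decreases_optimum(self, toy_economy):
        problem = build_lp(toy_economy, ORGANIC)
        base = solve_lp(problem).objective
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(problem.endowments), size=5, replace=False):
            relaxed = copy.deepcopy(problem)
            relaxed.endowments[idx] *= 1.5
            if relaxed.endowments[idx] == 0:
                relaxed.endowments[idx] = 1.0
            assert solve_lp(relaxed).objective >= base - 1e-6 * max(base, 1.0)

    def test_area_conservation_and_nonnegativity(self, toy_economy, toy_solutions):
        class_area = {lc.key: lc.area for lc in toy_economy.land_classes}
        for sol in toy_solutions.values():
            used = {}
            for a, v in sol.activity_levels.items():
                assert v >= 0
                if a[0] == "crop":
                    used[a[3]] = used.get(a[3], 0.0) + v
            for key, u in used.items():
                assert u <= class_area[key] * (1 + 1e-9) + 1e-6

    def test_infeasible_problem_reports_violated_rows(self):
        econ = one_class_economy([simple_crop("wheat", 8.0, 13.0)])
        problem = build_lp(econ, ORGANIC)
        # force an impossible row: require negative total area
        problem.constraint_matrix = np.vstack(
            [problem.constraint_matrix, -np.ones((1, problem.constraint_matrix.shape[1]))]
        )
        problem.endowments = np.append(problem.endowments, -1e9)
        problem.row_ids.append("impossible")
        problem.senses.append("<=")
        sol = solve_lp(problem)
        assert sol.status == "infeasible"
        assert "impossible" in sol.binding_constraints


class TestNationalProduction:
    def test_single_solution_identity(self, toy_solutions):
        sol = toy_solutions[CONVENTIONAL]
        assert national_production([sol]) == pytest.approx(sol.production)

    def test_additivity_across_farm_type_solutions(self):
        a = LandUseSolution({}, {"wheat": 40.0}, 10.0, [], "optimal")
        b = LandUseSolution({}, {"wheat": 60.0}, 20.0, [], "optimal")
        assert national_production([a, b])["wheat"] == pytest.approx(100.0)

    def test_refuses_non_optimal_inputs(self):
        bad = LandUseSolution({}, {}, float("nan"), [], "infeasible")
        with pytest.raises(ValueError):
            national_production([bad])

    def test_organic_output_bounded_by_yield_gap(self):
        # organic yields 60% of conventional and leys claim land for N, so
        # the organic/conventional ME ratio cannot exceed the yield ratio
        cereal = CropActivity(
            commodity="wheat",
            yield_by_class={
                CONVENTIONAL: {"medium:medium": 10.0},
                ORGANIC: {"medium:medium": 6.0},
            },
            me_coefficient=13.0, n_offtake=20.0,
        )
        ley = CropActivity(
            commodity="ley",
            yield_by_class={s: {"medium:medium": 8.0} for s in SYSTEMS},
            me_coefficient=10.0, n_offtake=0.0, n_fixation=200.0,
            rotation_group="forage", use="forage", is_legume=True,
        )
        econ = one_class_economy([cereal, ley], n_deposition=0.0)
        conv = solve_lp(build_lp(econ, CONVENTIONAL)).objective
        org = solve_lp(build_lp(econ, ORGANIC)).objective
        assert org / conv < 0.6 + 1e-9
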