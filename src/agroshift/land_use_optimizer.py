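"""Linear-programming land allocation: maximise national food-energy output.

The model allocates each farm type's fixed land base across crop and
livestock activities to maximise total metabolisable energy (ME) of food
production,

    max Z = sum_ij C_ij x_ij   s.t.  R x <= b,  x >= 0,

where activities x are crop areas (ha, by commodity and soil x rainfall
class) and livestock numbers (head), and the rows of R express: land
availability per class, rotational limits on crop-group shares, national
output caps at 150% of baseline supply, a per-farm-type nitrogen balance
(offtake must be covered by fixation, deposition, recycled manure and — in
conventional systems only — manufactured fertiliser), forage and concentrate
feed-energy balances, and stocking-density bounds.  Organic systems differ
by their coefficient set: lower yields, no manufactured N, so fertility
hinges on legumes and leys.

The LP is solved with the deterministic HiGHS solver; solutions are vertex
solutions and may be non-unique, so downstream claims rest on the objective
value and aggregate production, not on individual activity levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .synthetic_data import CAP_MULTIPLIER, CONVENTIONAL, Economy, SYSTEMS

__all__ = [
    "ConfigurationError",
    "LPProblem",
    "LandUseSolution",
    "build_lp",
    "solve_lp",
    "national_production",
]

FEASIBILITY_TOL = 1e-9
BINDING_TOL = 1e-6


class ConfigurationError(ValueError):
    """A coefficient required by an enabled activity/class pair is missing."""


@dataclass
class LPProblem:
    """Matrix form of the land-use LP (maximisation, rows all <=)."""

    objective_coefficients: np.ndarray  # GJ ME per unit activity
    activities: list[tuple]  # activity identifiers, parallel to columns
    constraint_matrix: np.ndarray  # R
    endowments: np.ndarray  # b
    senses: list[str]  # per-row, always "<=" here
    row_ids: list[str]
    # (commodity, t output per unit activity) or None, parallel to columns
    production_coefficients: list[tuple[str, float] | None] = field(default_factory=list)
    system: str = CONVENTIONAL

    def __post_init__(self) -> None:
        n_rows, n_cols = self.constraint_matrix.shape
        if len(self.objective_coefficients) != n_cols or len(self.activities) != n_cols:
            raise ValueError("inconsistent column dimensions")
        if len(self.endowments) != n_rows or len(self.row_ids) != n_rows:
            raise ValueError("inconsistent row dimensions")


@dataclass
class LandUseSolution:
    """Solved activity levels and the production they imply."""

    activity_levels: dict[tuple, float]
    production: dict[str, float]  # commodity -> t yr^-1
    objective: float  # GJ ME yr^-1
    binding_constraints: list[str]
    status: str  # optimal | infeasible | unbounded
    area_by_commodity: dict[str, float] = field(default_factory=dict)
    system: str = CONVENTIONAL


def build_lp(economy: Economy, system: str, apply_caps: bool | None = None) -> LPProblem:
    """Assemble the LP for one management system across all farm types.

    Columns are (crop, farm type, land class) areas, (livestock, farm type)
    head counts and, for conventional systems, one manufactured-N purchase
    variable per farm type.  Caps apply to both systems by default
    (configurable through ``economy.params.caps_apply_to_conventional``).
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")
    if apply_caps is None:
        apply_caps = system != CONVENTIONAL or economy.params.caps_apply_to_conventional

    p = economy.params
    activities: list[tuple] = []
    objective: list[float] = []
    production: list[tuple[str, float] | None] = []

    for ft in economy.farm_types:
        for crop in economy.crop_activities:
            if system not in crop.yield_by_class:
                raise ConfigurationError(
                    f"no {system} yields configured for crop {crop.commodity!r}"
                )
            for key, area in ft.land_by_class.items():
                if area <= 0:
                    continue
                if key not in crop.yield_by_class[system]:
                    raise ConfigurationError(
                        f"missing yield for ({crop.commodity!r}, {key!r}) under {system}"
                    )
                y = crop.yield_by_class[system][key]
                activities.append(("crop", ft.name, crop.commodity, key))
                objective.append(y * crop.me_coefficient if crop.use == "food" else 0.0)
                production.append((crop.commodity, y) if crop.use == "food" else None)
        for ls in economy.livestock_activities:
            if system not in ls.product_yield:
                raise ConfigurationError(
                    f"no {system} product yield configured for {ls.species!r}"
                )
            activities.append(("livestock", ft.name, ls.species))
            py = ls.product_yield[system]
            objective.append(py * ls.product_me)
            production.append((ls.species, py))
        if system == CONVENTIONAL:
            activities.append(("fertilizer", ft.name))
            objective.append(0.0)
            production.append(None)

    col = {a: i for i, a in enumerate(activities)}
    n = len(activities)
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    row_ids: list[str] = []

    def add_row(row: np.ndarray, b: float, rid: str) -> None:
        rows.append(row)
        rhs.append(b)
        row_ids.append(rid)

    for ft in economy.farm_types:
        # land availability per class
        for key, area in ft.land_by_class.items():
            if area <= 0:
                continue
            row = np.zeros(n)
            for crop in economy.crop_activities:
                a = ("crop", ft.name, crop.commodity, key)
                if a in col:
                    row[col[a]] = 1.0
            add_row(row, area, f"land:{ft.name}:{key}")

        # rotational crop-group share limits
        groups = sorted({c.rotation_group for c in economy.crop_activities})
        for g in groups:
            share = p.rotation_max_share.get(g, 1.0)
            if share >= 1.0:
                continue
            row = np.zeros(n)
            for crop in economy.crop_activities:
                if crop.rotation_group != g:
                    continue
                for key in ft.land_by_class:
                    a = ("crop", ft.name, crop.commodity, key)
                    if a in col:
                        row[col[a]] = 1.0
            add_row(row, share * ft.total_area, f"rotation:{ft.name}:{g}")

        # nitrogen balance: offtake - fixation - recycled manure - fertiliser
        # <= atmospheric deposition over the farm's area
        row = np.zeros(n)
        nonzero = False
        for crop in economy.crop_activities:
            for key in ft.land_by_class:
                a = ("crop", ft.name, crop.commodity, key)
                if a not in col:
                    continue
                y = crop.yield_by_class[system][key]
                coeff = crop.n_offtake * y - crop.n_fixation
                if coeff != 0.0:
                    row[col[a]] = coeff
                    nonzero = True
        for ls in economy.livestock_activities:
            a = ("livestock", ft.name, ls.species)
            row[col[a]] -= p.manure_recovery * ls.n_excretion
            nonzero = True
        if system == CONVENTIONAL:
            row[col[("fertilizer", ft.name)]] = -1.0
        if nonzero:
            add_row(row, p.n_deposition * ft.total_area, f"nitrogen:{ft.name}")

        # feed energy balances: demand - on-farm supply <= 0
        if economy.livestock_activities:
            forage_row = np.zeros(n)
            conc_row = np.zeros(n)
            for ls in economy.livestock_activities:
                a = ("livestock", ft.name, ls.species)
                forage_row[col[a]] = ls.forage_share * ls.me_feed_demand
                conc_row[col[a]] = (1.0 - ls.forage_share) * ls.me_feed_demand
            for crop in economy.crop_activities:
                if crop.use not in ("forage", "feed_grain"):
                    continue
                target = forage_row if crop.use == "forage" else conc_row
                for key in ft.land_by_class:
                    a = ("crop", ft.name, crop.commodity, key)
                    if a in col:
                        y = crop.yield_by_class[system][key]
                        target[col[a]] -= y * crop.me_coefficient
            add_row(forage_row, 0.0, f"feed_forage:{ft.name}")
            add_row(conc_row, 0.0, f"feed_concentrate:{ft.name}")

            # stocking density bounds relative to the farm's forage area
            forage_cols = [
                col[("crop", ft.name, crop.commodity, key)]
                for crop in economy.crops_by_use("forage")
                for key in ft.land_by_class
                if ("crop", ft.name, crop.commodity, key) in col
            ]
            for ls in economy.livestock_activities:
                a = col[("livestock", ft.name, ls.species)]
                row = np.zeros(n)
                row[a] = 1.0
                for c_idx in forage_cols:
                    row[c_idx] -= ls.stocking_max
                add_row(row, 0.0, f"stocking_max:{ft.name}:{ls.species}")
                if ls.stocking_min > 0:
                    row = np.zeros(n)
                    row[a] = -1.0
                    for c_idx in forage_cols:
                        row[c_idx] += ls.stocking_min
                    add_row(row, 0.0, f"stocking_min:{ft.name}:{ls.species}")

    # national output caps at 150% of baseline supply
    if apply_caps:
        cap_items: list[tuple[str, float]] = [
            (c.commodity, c.baseline_supply)
            for c in economy.crops_by_use("food")
            if np.isfinite(c.baseline_supply)
        ] + [
            (l.species, l.baseline_supply)
            for l in economy.livestock_activities
            if np.isfinite(l.baseline_supply)
        ]
        for commodity, baseline in cap_items:
            row = np.zeros(n)
            for i, prod in enumerate(production):
                if prod is not None and prod[0] == commodity:
                    row[i] = prod[1]
            add_row(row, CAP_MULTIPLIER * baseline, f"cap:{commodity}")

    matrix = np.vstack(rows) if rows else np.zeros((0, n))
    return LPProblem(
        objective_coefficients=np.asarray(objective, dtype=float),
        activities=activities,
        constraint_matrix=matrix,
        endowments=np.asarray(rhs, dtype=float),
        senses=["<="] * len(rhs),
        row_ids=row_ids,
        production_coefficients=production,
        system=system,
    )


def _violated_rows(problem: LPProblem) -> list[str]:
    """Diagnose infeasibility: minimise total constraint violation with
    elastic slacks and report the rows that remain violated."""
    n_rows, n_cols = problem.constraint_matrix.shape
    # variables: [x, s]; minimise sum(s) s.t. A x - s <= b
    c = np.concatenate([np.zeros(n_cols), np.ones(n_rows)])
    a_ub = np.hstack([problem.constraint_matrix, -np.eye(n_rows)])
    res = linprog(c, A_ub=a_ub, b_ub=problem.endowments, method="highs")
    if not res.success:
        return []
    slacks = res.x[n_cols:]
    return [rid for rid, s in zip(problem.row_ids, slacks) if s > 1e-7]


def solve_lp(problem: LPProblem) -> LandUseSolution:
    """Solve the LP; on infeasibility report the violated resource rows.

    The objective is maximised (HiGHS minimises its negation).  Production is
    reconstructed from the activity levels, and rows with slack below 1e-6
    (scaled) are flagged as binding.
    """
    res = linprog(
        -problem.objective_coefficients,
        A_ub=problem.constraint_matrix,
        b_ub=problem.endowments,
        bounds=(0, None),
        method="highs",
    )
    if res.status == 2:
        return LandUseSolution(
            activity_levels={},
            production={},
            objective=float("nan"),
            binding_constraints=_violated_rows(problem),
            status="infeasible",
            system=problem.system,
        )
    if res.status == 3:
        return LandUseSolution(
            activity_levels={}, production={}, objective=float("inf"),
            binding_constraints=[], status="unbounded", system=problem.system,
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")

    x = np.maximum(res.x, 0.0)
    levels = {a: float(v) for a, v in zip(problem.activities, x)}
    production: dict[str, float] = {}
    for i, prod in enumerate(problem.production_coefficients):
        if prod is not None:
            commodity, per_unit = prod
            production[commodity] = production.get(commodity, 0.0) + per_unit * x[i]
    area: dict[str, float] = {}
    for a, v in levels.items():
        if a[0] == "crop" and v > 0:
            area[a[2]] = area.get(a[2], 0.0) + v

    slack = problem.endowments - problem.constraint_matrix @ x
    scale = np.maximum(1.0, np.abs(problem.endowments))
    binding = [
        rid for rid, s, sc in zip(problem.row_ids, slack, scale) if s / sc <= BINDING_TOL
    ]
    return LandUseSolution(
        activity_levels=levels,
        production=production,
        objective=float(-res.fun),
        binding_constraints=binding,
        status="optimal",
        area_by_commodity=area,
        system=problem.system,
    )


def national_production(solutions: Sequence[LandUseSolution]) -> dict[str, float]:
    """Sum commodity production over per-farm-type (or per-region) solutions.

    Refuses to aggregate unless every solution is optimal; total ME equals
    the sum of the solutions' objectives by construction.
    """
    bad = [s.status for s in solutions if s.status != "optimal"]
    if bad:
        raise ValueError(f"cannot aggregate non-optimal solutions (statuses: {bad})")
    totals: dict[str, float] = {}
    for s in solutions:
        for commodity, t in s.production.items():
            totals[commodity] = totals.get(commodity, 0.0) + t
    return totals
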