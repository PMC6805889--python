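"""End-to-end orchestration: economy -> LP -> LCA -> trade -> budgets -> MC.

The pipeline mirrors the structure of a national organic-conversion
assessment: solve the land-use LP under conventional and organic management,
derive per-commodity farm-gate emission profiles, balance production against
demand to get trade flows and overseas land requirements, assemble net GHG
budgets under the High/Medium/Low land-use-change scenarios (with optional
carbon opportunity cost), propagate input uncertainty by Monte Carlo and
test scenario-vs-baseline differences with the z statistic.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lca_engine, land_use_optimizer as luo, trade_balance as tb
from .luc_accounting import (
    SCENARIOS, BudgetRow, ScenarioSpec, carbon_opportunity_cost,
    luc_emissions, net_budget, sequestration_offset,
)
from .synthetic_data import CONVENTIONAL, ORGANIC, Economy, EconomySpec, generate_economy
from .uncertainty import UncertaintySpec, ZTestInput, combine_components, cv_percent, z_test

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "assemble_budgets", "report_budget"]

logger = logging.getLogger("agroshift")

KG_PER_MT = 1e9
T_PER_MT = 1e6


@dataclass
class RunConfig:
    """One reproducible run: where the economy comes from and what to compute."""

    seed: int
    economy_dir: str | None = None
    spec: EconomySpec = field(default_factory=EconomySpec)
    scenarios: tuple[str, ...] = ("High", "Medium", "Low")
    include_coc: bool = False
    uncertainty: UncertaintySpec | None = None
    out_dir: str | None = None

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "economy_dir": self.economy_dir,
            "spec": dataclasses.asdict(self.spec),
            "scenarios": list(self.scenarios),
            "include_coc": self.include_coc,
            "uncertainty": dataclasses.asdict(self.uncertainty) if self.uncertainty else None,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    economy: Economy
    solutions: dict[str, luo.LandUseSolution]
    profiles: dict[str, dict[str, lca_engine.EmissionProfile]]
    flows: dict[str, list[tb.TradeFlow]]
    budget: list[BudgetRow]
    z_tests: pd.DataFrame
    production_comparison: pd.DataFrame


def _direct_emissions_by_gas(
    production: dict[str, float],
    exports: dict[str, float],
    profiles: dict[str, lca_engine.EmissionProfile],
    gwp: lca_engine.GwpSet,
) -> tuple[dict[str, float], dict[str, float]]:
    """Net domestic emissions by gas (Mt CO2e) and per-commodity CO2e totals.

    Export burdens are subtracted: only production serving domestic demand
    counts toward the national total.
    """
    by_gas = {"co2": 0.0, "ch4": 0.0, "n2o": 0.0}
    by_commodity: dict[str, float] = {}
    for commodity, t in production.items():
        prof = profiles.get(commodity)
        if prof is None or t <= 0:
            continue
        net_t = max(t - exports.get(commodity, 0.0), 0.0)
        by_gas["co2"] += prof.co2 * net_t / KG_PER_MT
        by_gas["ch4"] += prof.ch4 * net_t * gwp.gwp_ch4 / KG_PER_MT
        by_gas["n2o"] += prof.n2o * net_t * gwp.gwp_n2o / KG_PER_MT
        by_commodity[commodity] = prof.co2e * net_t / KG_PER_MT
    return by_gas, by_commodity


def _build_flows(
    economy: Economy, production: dict[str, float]
) -> list[tb.TradeFlow]:
    flows = []
    for commodity, demand in sorted(economy.demand.items()):
        flow = tb.make_trade_flow(
            commodity, production.get(commodity, 0.0), demand,
            economy.import_origins.get(commodity),
        )
        if flow.imports > 0:
            tb.import_transport_emissions(flow, economy.transport_coefficients)
        flows.append(flow)
    return flows


def assemble_budgets(
    economy: Economy,
    solutions: dict[str, luo.LandUseSolution],
    profiles: dict[str, dict[str, lca_engine.EmissionProfile]],
    flows: dict[str, list[tb.TradeFlow]],
    scenarios: tuple[str, ...] = ("High", "Medium", "Low"),
    include_coc: bool = False,
    uspec: UncertaintySpec | None = None,
    seed: int = 0,
    gwp: lca_engine.GwpSet | None = None,
) -> tuple[list[BudgetRow], pd.DataFrame]:
    """National budget rows (baseline + one per scenario) and z-test table.

    The conventional row is the baseline: direct + transport only.  Each
    organic scenario adds overseas import-production emissions, LUC from the
    additional overseas area, a soil-carbon credit on organically managed
    arable land at home and overseas, and (optionally) the carbon opportunity
    cost of the additional imports.  Monte-Carlo uncertainty uses triangular
    half-widths per component: 10% per domestic crop, 15% per livestock, 15%
    for imports en bloc, 10% transport, 17% LUC, 86%/24% sequestration, 26%
    COC.
    """
    gwp = gwp or lca_engine.GwpSet()
    uspec = uspec or UncertaintySpec()
    crop_names = {c.commodity for c in economy.crops_by_use("food")}
    seeds = np.random.SeedSequence(seed).spawn(len(scenarios) + 1)

    # conventional baseline ------------------------------------------------
    conv_sol = solutions[CONVENTIONAL]
    conv_exports = {f.commodity: f.exports for f in flows[CONVENTIONAL]}
    conv_gas, conv_by_commodity = _direct_emissions_by_gas(
        conv_sol.production, conv_exports, profiles[CONVENTIONAL], gwp
    )
    conv_transport = sum(f.transport_emissions for f in flows[CONVENTIONAL]) / KG_PER_MT
    conv_direct = sum(conv_gas.values())
    conv_total = conv_direct + conv_transport

    conv_components = [
        (mt, uspec.cv_domestic_crop if c in crop_names else uspec.cv_domestic_livestock)
        for c, mt in sorted(conv_by_commodity.items())
    ] + [(conv_transport, uspec.cv_transport)]
    conv_mean, conv_sd = combine_components(
        conv_components, None, uspec.n_sims, np.random.default_rng(seeds[0])
    )

    baseline_row = BudgetRow(
        scenario="Conventional",
        total=conv_total,
        sd=conv_sd,
        components={
            "direct": conv_direct, "transport": conv_transport,
            "luc": 0.0, "sequestration": 0.0, "coc": 0.0,
        },
        gas_fractions=_gas_fractions(conv_gas, extra_co2=conv_transport),
        pct_change_vs_baseline=0.0,
    )
    rows = [baseline_row]
    ztab_rows = []

    # organic scenarios ----------------------------------------------------
    org_sol = solutions[ORGANIC]
    org_flows = flows[ORGANIC]
    org_exports = {f.commodity: f.exports for f in org_flows}
    org_gas, org_by_commodity = _direct_emissions_by_gas(
        org_sol.production, org_exports, profiles[ORGANIC], gwp
    )
    org_direct = sum(org_gas.values())
    org_transport = sum(f.transport_emissions for f in org_flows) / KG_PER_MT

    # imported shortfalls are produced organically overseas; region
    # archetypes default to the domestic organic profile (conventional as
    # fallback when a commodity is not produced domestically at all)
    import_gas = {"co2": 0.0, "ch4": 0.0, "n2o": 0.0}
    import_total = 0.0
    for f in org_flows:
        if f.imports <= 0:
            continue
        prof = profiles[ORGANIC].get(f.commodity) or profiles[CONVENTIONAL].get(f.commodity)
        if prof is None:
            continue
        import_gas["co2"] += prof.co2 * f.imports / KG_PER_MT
        import_gas["ch4"] += prof.ch4 * f.imports * gwp.gwp_ch4 / KG_PER_MT
        import_gas["n2o"] += prof.n2o * f.imports * gwp.gwp_n2o / KG_PER_MT
        import_total += prof.co2e * f.imports / KG_PER_MT

    baseline_areas = {
        (f.commodity, o): a
        for f in flows[CONVENTIONAL]
        for o, a in f.overseas_area.items()
    }
    total_overseas, additional_overseas = tb.overseas_land_requirement(
        org_flows, economy.overseas_yields, baseline_areas
    )
    additional_by_origin: dict[str, float] = {}
    for f in org_flows:
        for origin, area in f.overseas_area.items():
            base = baseline_areas.get((f.commodity, origin), 0.0)
            additional_by_origin[origin] = additional_by_origin.get(origin, 0.0) + max(
                area - base, 0.0
            )
    home_eligible = sum(org_sol.area_by_commodity.values())
    additional_imports = {f.commodity: f.imports for f in org_flows if f.imports > 0}
    coc_mt = carbon_opportunity_cost(additional_imports, economy.coc_factors) / T_PER_MT

    for i, name in enumerate(scenarios):
        scenario: ScenarioSpec = SCENARIOS[name]
        luc_mt = luc_emissions(additional_by_origin, scenario, economy.luc_factors) / T_PER_MT
        seq_mt = sequestration_offset(home_eligible, total_overseas, scenario)
        direct_with_imports = org_direct + import_total
        total, pct = net_budget(
            direct_with_imports, org_transport, luc_mt, seq_mt,
            baseline=conv_total, coc=coc_mt, include_coc=include_coc,
        )
        gas = {
            "co2": org_gas["co2"] + import_gas["co2"] + org_transport + luc_mt + seq_mt
            + (coc_mt if include_coc else 0.0),
            "ch4": org_gas["ch4"] + import_gas["ch4"],
            "n2o": org_gas["n2o"] + import_gas["n2o"],
        }
        components = [
            (mt, uspec.cv_domestic_crop if c in crop_names else uspec.cv_domestic_livestock)
            for c, mt in sorted(org_by_commodity.items())
        ]
        components += [
            (import_total, uspec.cv_imports_en_bloc),
            (org_transport, uspec.cv_transport),
            (luc_mt, uspec.cv_luc),
            (seq_mt, uspec.seq_cv(scenario.seq_rate)),
        ]
        if include_coc:
            components.append((coc_mt, uspec.cv_coc))
        mean, sd = combine_components(
            components, None, uspec.n_sims, np.random.default_rng(seeds[i + 1])
        )
        zres = z_test(
            ZTestInput(
                m_a=conv_total, m_b=max(total, 1e-12),
                cv_a=cv_percent(conv_total, conv_sd),
                cv_b=cv_percent(max(total, 1e-12), sd),
            )
        )
        rows.append(
            BudgetRow(
                scenario=name,
                total=total,
                sd=sd,
                components={
                    "direct": direct_with_imports, "transport": org_transport,
                    "luc": luc_mt, "sequestration": seq_mt,
                    "coc": coc_mt if include_coc else 0.0,
                },
                gas_fractions=_gas_fractions(gas),
                pct_change_vs_baseline=pct,
                significant=zres.significant,
            )
        )
        ztab_rows.append(
            {
                "pair": f"Conventional vs {name}",
                "m_a": conv_total, "m_b": total,
                "sd_a": conv_sd, "sd_b": sd,
                "z": zres.z, "significant": zres.significant,
            }
        )
    return rows, pd.DataFrame(ztab_rows)


def _gas_fractions(gas: dict[str, float], extra_co2: float = 0.0) -> dict[str, float]:
    """Percent of the net total by gas (CO2 including transport/LUC/credits)."""
    co2 = gas["co2"] + extra_co2
    total = co2 + gas["ch4"] + gas["n2o"]
    if total == 0:
        return {"co2": 0.0, "ch4": 0.0, "n2o": 0.0}
    return {
        "co2": 100.0 * co2 / total,
        "ch4": 100.0 * gas["ch4"] / total,
        "n2o": 100.0 * gas["n2o"] / total,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order; write artifacts if out_dir is set.

    Stage failures abort with the stage name in the exception message.
    Reruns with the same config produce identical outputs.
    """
    stage = "load economy"
    try:
        if config.economy_dir:
            economy = Economy.from_dir(config.economy_dir)
        else:
            economy = generate_economy(config.spec, config.seed)

        solutions: dict[str, luo.LandUseSolution] = {}
        profiles: dict[str, dict[str, lca_engine.EmissionProfile]] = {}
        flows: dict[str, list[tb.TradeFlow]] = {}
        for system in (CONVENTIONAL, ORGANIC):
            stage = f"optimize ({system})"
            logger.info("stage %s", stage)
            sol = luo.solve_lp(luo.build_lp(economy, system))
            if sol.status != "optimal":
                raise RuntimeError(
                    f"{system} LP is {sol.status}; violated rows: {sol.binding_constraints}"
                )
            solutions[system] = sol
            stage = f"lca ({system})"
            profiles[system] = lca_engine.commodity_emissions(economy, sol, system)
            stage = f"trade ({system})"
            sys_flows = _build_flows(economy, sol.production)
            tb.overseas_land_requirement(sys_flows, economy.overseas_yields)
            flows[system] = sys_flows

        stage = "budget"
        budget, ztab = assemble_budgets(
            economy, solutions, profiles, flows,
            scenarios=config.scenarios, include_coc=config.include_coc,
            uspec=config.uncertainty, seed=config.seed,
        )

        stage = "report"
        comparison = pd.DataFrame(
            {
                "commodity": sorted(
                    set(solutions[CONVENTIONAL].production) | set(solutions[ORGANIC].production)
                )
            }
        )
        comparison["conventional_t"] = [
            solutions[CONVENTIONAL].production.get(c, 0.0) for c in comparison.commodity
        ]
        comparison["organic_t"] = [
            solutions[ORGANIC].production.get(c, 0.0) for c in comparison.commodity
        ]
        comparison["ratio"] = np.where(
            comparison.conventional_t > 0,
            comparison.organic_t / comparison.conventional_t,
            np.nan,
        )

        result = PipelineResult(
            economy=economy, solutions=solutions, profiles=profiles,
            flows=flows, budget=budget, z_tests=ztab,
            production_comparison=comparison,
        )
        if config.out_dir:
            stage = "write outputs"
            _write_outputs(config, result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def report_budget(budget: list[BudgetRow], baseline: str = "Conventional") -> pd.DataFrame:
    """Paper-style budget table: totals +- sd, gas fractions, % change.

    Totals and sds print at one decimal (Mt), fractions and percent changes
    as integers; significance is marked for non-baseline rows.
    """
    if not any(r.scenario == baseline for r in budget):
        raise ValueError(f"baseline {baseline!r} not in budget")
    rows = []
    for r in budget:
        rows.append(
            {
                "scenario": r.scenario,
                "emissions_mt": round(r.total, 1),
                "sd_mt": round(r.sd, 1),
                "frac_co2_pct": round(r.gas_fractions.get("co2", 0.0)),
                "frac_ch4_pct": round(r.gas_fractions.get("ch4", 0.0)),
                "frac_n2o_pct": round(r.gas_fractions.get("n2o", 0.0)),
                "pct_change_vs_baseline": int(round(r.pct_change_vs_baseline or 0)),
                "significance": (
                    "" if r.scenario == baseline
                    else ("p < 0.05" if r.significant else "NS")
                ),
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(config: RunConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.production_comparison.to_csv(out / "production_comparison.csv", index=False)
    prof_rows = [
        {
            "commodity": p.commodity, "system": p.system,
            "co2": p.co2, "ch4": p.ch4, "n2o": p.n2o, "co2e": p.co2e,
        }
        for system in result.profiles
        for p in result.profiles[system].values()
    ]
    pd.DataFrame(prof_rows).to_csv(out / "emission_profiles.csv", index=False)
    pd.concat(
        [tb.trade_flows_frame(result.flows[s]).assign(system=s) for s in result.flows]
    ).to_csv(out / "trade_flows.csv", index=False)
    budget_rows = []
    for r in result.budget:
        for comp, mt in r.components.items():
            budget_rows.append(
                {
                    "scenario": r.scenario, "component": comp, "mt_co2e": mt,
                    "sd": r.sd,
                    "frac_co2": r.gas_fractions.get("co2", 0.0),
                    "frac_ch4": r.gas_fractions.get("ch4", 0.0),
                    "frac_n2o": r.gas_fractions.get("n2o", 0.0),
                }
            )
    pd.DataFrame(budget_rows).to_csv(out / "budget.csv", index=False)
    report_budget(result.budget).to_csv(out / "budget_table.csv", index=False)
    result.z_tests.to_csv(out / "z_tests.csv", index=False)
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "package": "agroshift 0.1.0",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
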