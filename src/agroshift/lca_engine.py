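"""Cradle-to-farm-gate greenhouse-gas accounting per commodity.

For each commodity and management system the engine assembles CO2 (fossil
energy, input manufacture), N2O (soil emissions from applied and deposited
nitrogen, following IPCC-2006-style direct and indirect pathways) and CH4
(enteric fermentation, manure management), divides by production to get
per-tonne emission intensities, and aggregates the three gases to CO2
equivalents with 100-year global warming potentials.  The system boundary is
the farm gate: on-farm processing energy is inside it, distribution and
consumption are not.

Allocation rules: shared burdens split between co-products in proportion to
economic value (mass x unit price, with an optional organic price
differential); manure is handled by system expansion — in conventional
accounting the manufactured fertiliser N it displaces is credited back; all
burdens of feed production land on the livestock consuming the feed, never
on the crop sector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .land_use_optimizer import LandUseSolution
from .synthetic_data import CONVENTIONAL, Economy

__all__ = [
    "GwpSet",
    "EmissionFactorSet",
    "EntericParams",
    "EmissionProfile",
    "soil_n2o",
    "enteric_ch4",
    "allocate_coproducts",
    "manure_system_expansion",
    "aggregate_gwp",
    "commodity_emissions",
]

N2O_PER_N = 44.0 / 28.0  # molar mass ratio N2O / N2


@dataclass(frozen=True)
class GwpSet:
    """100-year global warming potentials (kg CO2e per kg gas)."""

    gwp_ch4: float = 25.0
    gwp_n2o: float = 298.0
    horizon: int = 100

    def __post_init__(self) -> None:
        if self.gwp_ch4 <= 0 or self.gwp_n2o <= 0:
            raise ValueError("GWPs must be positive")
        if self.horizon != 100:
            raise ValueError("only the 100-year horizon is supported")


@dataclass(frozen=True)
class EmissionFactorSet:
    """IPCC-2006-style Tier 1 N2O factors (all configurable).

    ef_direct: fraction of applied N emitted directly as N2O-N.
    frac_leach / ef_leach: fraction of N leached and its N2O-N factor.
    frac_volat_*: volatilised fractions for synthetic and manure N, with a
    common indirect factor ef_volat.  leach_step is added to frac_leach once
    for heavy soils and once for very-wet rainfall classes.
    """

    ef_direct: float = 0.01
    frac_leach: float = 0.30
    ef_leach: float = 0.0075
    frac_volat_synthetic: float = 0.10
    frac_volat_manure: float = 0.20
    ef_volat: float = 0.010
    leach_step: float = 0.15

    def leach_fraction_for(self, soil_class: str, rainfall_class: str) -> float:
        frac = self.frac_leach
        if soil_class == "heavy":
            frac += self.leach_step
        if rainfall_class == "very_wet":
            frac += self.leach_step
        return min(frac, 1.0)


@dataclass(frozen=True)
class EntericParams:
    """Enteric CH4 model coefficients.

    Methane yield per kg dry matter intake interpolates between the
    concentrate and forage factors with the forage share of the diet
    (forage >= concentrate, so more forage means more CH4 at equal intake).
    Live-weight and milk-yield enter as multiplicative adjustments that equal
    1 at the reference animal, keeping CH4 exactly linear in intake.
    """

    methane_yield_concentrate: float = 0.018  # kg CH4 per kg DM
    methane_yield_forage: float = 0.023
    liveweight_ref: float = 500.0  # kg
    liveweight_coeff: float = 0.0002  # per kg deviation from reference
    milk_coeff: float = 0.005  # per t fat-corrected milk per yr

    def __post_init__(self) -> None:
        if self.methane_yield_forage < self.methane_yield_concentrate:
            raise ValueError("forage methane yield must be >= concentrate yield")


@dataclass
class EmissionProfile:
    """Per-tonne farm-gate emission intensities for one commodity/system.

    ``credit`` carries signed system-expansion credits (kg CO2e t^-1)
    separately; co2e aggregates the three gross gas components exactly.
    """

    commodity: str
    system: str
    co2: float  # kg CO2 t^-1
    ch4: float  # kg CH4 t^-1
    n2o: float  # kg N2O t^-1
    co2e: float  # kg CO2e t^-1
    credit: float = 0.0

    @classmethod
    def from_components(
        cls, commodity: str, system: str, co2: float, ch4: float, n2o: float,
        gwp: GwpSet, credit: float = 0.0,
    ) -> "EmissionProfile":
        if min(co2, ch4, n2o) < 0:
            raise ValueError("gas components must be >= 0 (credits are separate)")
        return cls(
            commodity=commodity, system=system, co2=co2, ch4=ch4, n2o=n2o,
            co2e=aggregate_gwp(co2, ch4, n2o, gwp), credit=credit,
        )


def soil_n2o(
    n_applied: Mapping[str, float],
    leach_fraction: float,
    ef: EmissionFactorSet | None = None,
) -> float:
    """Soil N2O from applied N (kg N2O ha^-1), direct plus indirect.

    ``n_applied`` maps source ("synthetic", "manure", ...) to kg N ha^-1.
    N2O-N = ef_direct * N + leach_fraction * N * ef_leach
          + frac_volat(source) * N * ef_volat, all times 44/28.
    Linear in every N input.
    """
    ef = ef or EmissionFactorSet()
    if not 0.0 <= leach_fraction <= 1.0:
        raise ValueError("leach fraction must be in [0, 1]")
    n2o_n = 0.0
    for source, n in n_applied.items():
        if n < 0:
            raise ValueError(f"negative N input for source {source!r}")
        frac_volat = (
            ef.frac_volat_manure if source == "manure" else ef.frac_volat_synthetic
        )
        n2o_n += n * (ef.ef_direct + leach_fraction * ef.ef_leach + frac_volat * ef.ef_volat)
    return n2o_n * N2O_PER_N


def enteric_ch4(
    dry_matter_intake: float,
    forage_share: float,
    liveweight: float = 500.0,
    milk_yield: float = 0.0,
    params: EntericParams | None = None,
) -> float:
    """Enteric CH4 per head (kg CH4 head^-1 yr^-1).

    Linear in dry matter intake; increasing in forage share at fixed intake.
    """
    params = params or EntericParams()
    if min(dry_matter_intake, liveweight, milk_yield) < 0:
        raise ValueError("inputs must be >= 0")
    if not 0.0 <= forage_share <= 1.0:
        raise ValueError("forage share must be in [0, 1]")
    methane_yield = params.methane_yield_concentrate + forage_share * (
        params.methane_yield_forage - params.methane_yield_concentrate
    )
    lw_adj = 1.0 + params.liveweight_coeff * (liveweight - params.liveweight_ref)
    milk_adj = 1.0 + params.milk_coeff * milk_yield
    return dry_matter_intake * methane_yield * max(lw_adj, 0.0) * milk_adj


def allocate_coproducts(
    total_burden: float,
    products: Sequence[tuple[float, float]],
    price_multipliers: Sequence[float] | None = None,
) -> list[float]:
    """Split a shared burden across co-products by economic value.

    ``products`` are (mass t, unit price) pairs; shares are proportional to
    mass x price (x an optional per-product multiplier, e.g. an organic price
    differential — a common multiplier cancels).  The allocated burdens sum
    to the total exactly.
    """
    if not products:
        raise ValueError("no products to allocate to")
    mult = list(price_multipliers) if price_multipliers is not None else [1.0] * len(products)
    if len(mult) != len(products):
        raise ValueError("one price multiplier per product required")
    values = [m * p * mu for (m, p), mu in zip(products, mult)]
    if any(v < 0 for v in values):
        raise ValueError("negative product value")
    total_value = sum(values)
    if total_value == 0:
        raise ValueError("all-zero product value: prices are misconfigured")
    return [total_burden * v / total_value for v in values]


def manure_system_expansion(manure_n: float, fertilizer_burden: float) -> float:
    """System-expansion credit for manure N (kg CO2e, positive = avoided).

    Manure N displaces manufactured fertiliser N in conventional accounting;
    the credit is manure available N x the manufacture burden per kg N.
    Organic systems use no manufactured N, so there is nothing to displace
    and the rule is inactive there.
    """
    if manure_n < 0 or fertilizer_burden < 0:
        raise ValueError("inputs must be >= 0")
    return manure_n * fertilizer_burden


def aggregate_gwp(co2: float, ch4: float, n2o: float, gwp: GwpSet | None = None) -> float:
    """kg CO2e = co2 + gwp_ch4 * ch4 + gwp_n2o * n2o (exactly linear)."""
    gwp = gwp or GwpSet()
    if min(co2, ch4, n2o) < 0:
        raise ValueError("components must be >= 0")
    return co2 + gwp.gwp_ch4 * ch4 + gwp.gwp_n2o * n2o


@dataclass
class _GasTotals:
    co2: float = 0.0
    ch4: float = 0.0
    n2o: float = 0.0

    def add(self, co2: float = 0.0, ch4: float = 0.0, n2o: float = 0.0) -> None:
        self.co2 += co2
        self.ch4 += ch4
        self.n2o += n2o


def commodity_emissions(
    economy: Economy,
    solution: LandUseSolution,
    system: str,
    ef: EmissionFactorSet | None = None,
    gwp: GwpSet | None = None,
    enteric: EntericParams | None = None,
) -> dict[str, EmissionProfile]:
    """Per-tonne emission profiles for every produced commodity.

    Crop activities contribute field-energy CO2, fertiliser-manufacture CO2
    (conventional only; manure N displaces fertiliser N first, which is the
    system-expansion credit in practice) and soil N2O from applied N.  Feed
    and forage crop burdens accumulate per farm type and are allocated to its
    livestock by feed-energy demand; livestock add enteric and manure CH4,
    manure N2O and housing/processing energy CO2.  A commodity with zero
    production but a nonzero burden has no allocation basis and is an error.
    """
    if solution.status != "optimal":
        raise ValueError("emissions require an optimal land-use solution")
    ef = ef or EmissionFactorSet()
    gwp = gwp or GwpSet()
    enteric = enteric or EntericParams()
    p = economy.params

    crops = {c.commodity: c for c in economy.crop_activities}
    soils = {lc.key: lc for lc in economy.land_classes}
    totals: dict[str, _GasTotals] = {}
    feed_pool: dict[str, _GasTotals] = {ft.name: _GasTotals() for ft in economy.farm_types}
    heads: dict[str, dict[str, float]] = {ft.name: {} for ft in economy.farm_types}
    fert_n: dict[str, float] = {}
    crop_n_demand: dict[str, dict[tuple, float]] = {}

    for activity, level in solution.activity_levels.items():
        if activity[0] == "livestock":
            _, ft_name, species = activity
            heads[ft_name][species] = heads[ft_name].get(species, 0.0) + level
        elif activity[0] == "fertilizer":
            fert_n[activity[1]] = level

    # apportion each farm's manure and fertiliser N over its crops by their
    # unmet N demand (offtake beyond own fixation)
    for activity, level in solution.activity_levels.items():
        if activity[0] != "crop" or level <= 0:
            continue
        _, ft_name, commodity, key = activity
        crop = crops[commodity]
        y = crop.yield_by_class[system][key]
        demand = max(crop.n_offtake * y - crop.n_fixation, 0.0) * level
        crop_n_demand.setdefault(ft_name, {})[activity] = demand

    manure_n_by_ft = {
        ft.name: sum(
            p.manure_recovery * ls.n_excretion * heads[ft.name].get(ls.species, 0.0)
            for ls in economy.livestock_activities
        )
        for ft in economy.farm_types
    }

    for ft in economy.farm_types:
        demands = crop_n_demand.get(ft.name, {})
        total_demand = sum(demands.values())
        manure_avail = manure_n_by_ft[ft.name]
        synthetic_avail = fert_n.get(ft.name, 0.0) if system == CONVENTIONAL else 0.0
        for activity, demand in demands.items():
            _, _, commodity, key = activity
            crop = crops[commodity]
            level = solution.activity_levels[activity]
            share = demand / total_demand if total_demand > 0 else 0.0
            manure_n = manure_avail * share
            synthetic_n = min(synthetic_avail * share, max(demand - manure_n, 0.0))
            lc = soils[key]
            leach = ef.leach_fraction_for(lc.soil_class, lc.rainfall_class)
            n2o = soil_n2o(
                {"synthetic": synthetic_n / level if level else 0.0,
                 "manure": manure_n / level if level else 0.0},
                leach, ef,
            ) * level
            co2 = crop.energy_co2_per_ha.get(system, 0.0) * level
            co2 += synthetic_n * p.fertilizer_co2e_per_kg_n  # manufacture burden
            target = (
                totals.setdefault(commodity, _GasTotals())
                if crop.use == "food"
                else feed_pool[ft.name]
            )
            target.add(co2=co2, n2o=n2o)
        # crops with no unmet N demand (legumes, leys) still burn field energy
        for activity, level in solution.activity_levels.items():
            if activity[0] != "crop" or activity[1] != ft.name or level <= 0:
                continue
            if activity in demands and demands[activity] > 0:
                continue
            _, _, commodity, key = activity
            crop = crops[commodity]
            co2 = crop.energy_co2_per_ha.get(system, 0.0) * level
            target = (
                totals.setdefault(commodity, _GasTotals())
                if crop.use == "food"
                else feed_pool[ft.name]
            )
            target.add(co2=co2)

        # livestock: enteric + manure CH4, manure N2O, energy CO2, feed burden
        ft_heads = heads[ft.name]
        total_feed_demand = sum(
            ls.me_feed_demand * ft_heads.get(ls.species, 0.0)
            for ls in economy.livestock_activities
        )
        for ls in economy.livestock_activities:
            h = ft_heads.get(ls.species, 0.0)
            if h <= 0:
                continue
            t = totals.setdefault(ls.species, _GasTotals())
            ch4 = (
                enteric_ch4(
                    ls.dry_matter_intake, ls.forage_share, ls.liveweight,
                    ls.milk_yield, enteric,
                )
                + ls.manure_ch4_per_head
            ) * h
            n2o = soil_n2o({"manure": ls.n_excretion}, ef.frac_leach, ef) * h
            co2 = ls.energy_co2_per_head.get(system, 0.0) * h
            t.add(co2=co2, ch4=ch4, n2o=n2o)
            if total_feed_demand > 0:
                share = ls.me_feed_demand * h / total_feed_demand
                pool = feed_pool[ft.name]
                t.add(co2=pool.co2 * share, ch4=pool.ch4 * share, n2o=pool.n2o * share)

    profiles: dict[str, EmissionProfile] = {}
    for commodity, t in totals.items():
        production = solution.production.get(commodity, 0.0)
        gross = t.co2 + t.ch4 + t.n2o
        if production <= 0:
            if gross > 0:
                raise ValueError(
                    f"{commodity!r} has emissions but zero production: "
                    "per-tonne allocation basis undefined"
                )
            continue
        profiles[commodity] = EmissionProfile.from_components(
            commodity, system,
            co2=t.co2 / production, ch4=t.ch4 / production, n2o=t.n2o / production,
            gwp=gwp,
        )
    return profiles
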