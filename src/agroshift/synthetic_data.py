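"""Synthetic miniature agricultural economies with known structure.

The national analysis needs, as input, a land base partitioned into soil x
rainfall classes and farm types, per-activity coefficients (yields,
metabolisable energy, nitrogen flows, emission intensities), a demand
baseline, and trade/land-use-change factor tables.  This module generates
self-consistent toy economies with that exact structure — small enough that
every downstream stage (LP optimisation, LCA, trade balancing, scenario
budgets) can be tested against hand-computable or brute-force ground truth,
with no external data.

Conventions: four soil classes (heavy, medium, light, humose) crossed with
four rainfall classes (dry, medium, wet, very_wet) give at most 16 land
classes.  Farm-type land areas are fixed once generated.  Two management
systems are parameterised for every activity: ``conventional`` (manufactured
N available, higher yields) and ``organic`` (biological N fixation only,
lower yields, fertility-building leys).  Crop output caps sit at 150% of the
baseline supply, reflecting limits on what the market can absorb.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SOIL_CLASSES",
    "RAINFALL_CLASSES",
    "DEFAULT_FARM_TYPE_NAMES",
    "CONVENTIONAL",
    "ORGANIC",
    "SYSTEMS",
    "LandClass",
    "FarmType",
    "CropActivity",
    "LivestockActivity",
    "EconomyParams",
    "Economy",
    "EconomySpec",
    "generate_economy",
    "generate_known_optimum_case",
]

SOIL_CLASSES = ("heavy", "medium", "light", "humose")
RAINFALL_CLASSES = ("dry", "medium", "wet", "very_wet")

# Robust Farm Type classification: the standard named set (configurable).
DEFAULT_FARM_TYPE_NAMES = (
    "specialist cropping",
    "mixed arable and livestock",
    "specialist dairy",
    "lowland grazing",
    "LFA grazing",
    "pigs",
    "poultry",
    "other",
)

CONVENTIONAL = "conventional"
ORGANIC = "organic"
SYSTEMS = (CONVENTIONAL, ORGANIC)

CAP_MULTIPLIER = 1.5  # output caps at 150% of baseline supply

_FOOD_CROP_POOL = (
    "wheat", "barley", "oats", "potatoes", "field beans", "oilseed rape",
    "sugar beet", "carrots", "onions", "rye", "peas", "cabbage",
)
_LEGUME_FOOD_CROPS = {"field beans", "peas"}
_ROTATION_GROUP = {
    "wheat": "cereals", "barley": "cereals", "oats": "cereals", "rye": "cereals",
    "potatoes": "roots", "sugar beet": "roots", "carrots": "roots",
    "onions": "roots", "cabbage": "roots",
    "field beans": "legumes", "peas": "legumes",
    "oilseed rape": "breaks",
}
_LIVESTOCK_POOL = ("dairy", "beef", "sheep", "pigs", "poultry", "eggs")


@dataclass(frozen=True)
class LandClass:
    """One soil x rainfall stratum of the land base."""

    soil_class: str
    rainfall_class: str
    area: float  # ha

    def __post_init__(self) -> None:
        if self.soil_class not in SOIL_CLASSES:
            raise ValueError(f"unknown soil class {self.soil_class!r}")
        if self.rainfall_class not in RAINFALL_CLASSES:
            raise ValueError(f"unknown rainfall class {self.rainfall_class!r}")
        if not np.isfinite(self.area) or self.area < 0:
            raise ValueError(f"area must be finite and >= 0, got {self.area}")

    @property
    def key(self) -> str:
        return f"{self.soil_class}:{self.rainfall_class}"


@dataclass
class FarmType:
    """A farm type with a fixed allocation of land across classes."""

    name: str
    land_by_class: dict[str, float]  # class key -> ha, fixed across scenarios

    @property
    def total_area(self) -> float:
        return sum(self.land_by_class.values())


@dataclass
class CropActivity:
    """A crop that can be grown on any land class of a farm type.

    ``use`` distinguishes marketed food crops (which carry ME into the
    objective and face demand/caps) from on-farm feed: ``forage`` (grass or
    grass-clover ley, feeding ruminants and building N) and ``feed_grain``
    (concentrate feed).  Yields, in t fresh weight ha^-1, are per management
    system and land class.
    """

    commodity: str
    yield_by_class: dict[str, dict[str, float]]  # system -> class key -> t/ha
    me_coefficient: float  # GJ ME per t fresh weight
    n_offtake: float  # kg N removed per t of product
    n_fixation: float = 0.0  # kg N ha^-1 fixed (legumes / leys only)
    rotation_group: str = "cereals"
    baseline_supply: float = float("inf")  # t yr^-1; inf disables the cap
    use: str = "food"
    energy_co2_per_ha: dict[str, float] = field(default_factory=dict)  # kg CO2/ha
    price: float = 1.0  # relative unit value (economic allocation)
    is_legume: bool = False

    def __post_init__(self) -> None:
        if self.me_coefficient <= 0:
            raise ValueError(f"{self.commodity}: me_coefficient must be > 0")
        if self.n_offtake < 0:
            raise ValueError(f"{self.commodity}: n_offtake must be >= 0")
        if not self.is_legume and self.n_fixation != 0:
            raise ValueError(f"{self.commodity}: n_fixation must be 0 for non-legumes")
        for system, by_class in self.yield_by_class.items():
            for key, y in by_class.items():
                if y < 0:
                    raise ValueError(f"{self.commodity}: negative yield for {system}/{key}")
        if self.use not in ("food", "forage", "feed_grain"):
            raise ValueError(f"{self.commodity}: unknown use {self.use!r}")


@dataclass
class LivestockActivity:
    """A livestock enterprise, sized in head (or head-equivalents) per year."""

    species: str
    me_feed_demand: float  # GJ ME head^-1 yr^-1
    diet_shares: tuple[float, float]  # (forage, concentrate), sums to 1
    product_yield: dict[str, float]  # system -> t product head^-1 yr^-1
    product_me: float  # GJ ME per t product
    n_excretion: float  # kg N head^-1 yr^-1
    mortality: float = 0.03  # fraction yr^-1
    stocking_min: float = 0.0  # head per forage ha
    stocking_max: float = 10.0
    baseline_supply: float = float("inf")  # t product yr^-1
    dry_matter_intake: float = 5000.0  # kg DM head^-1 yr^-1
    liveweight: float = 500.0  # kg
    milk_yield: float = 0.0  # t head^-1 yr^-1 (dairy only)
    energy_co2_per_head: dict[str, float] = field(default_factory=dict)  # kg CO2/head
    manure_ch4_per_head: float = 0.0  # kg CH4 head^-1 yr^-1 (manure management)
    price: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.diet_shares) - 1.0) > 1e-9:
            raise ValueError(f"{self.species}: diet shares must sum to 1")
        if not (0 <= self.diet_shares[0] <= 1):
            raise ValueError(f"{self.species}: forage share outside [0, 1]")
        if self.stocking_min > self.stocking_max:
            raise ValueError(f"{self.species}: stocking_min > stocking_max")

    @property
    def forage_share(self) -> float:
        return self.diet_shares[0]


@dataclass
class EconomyParams:
    """Economy-wide technical coefficients shared by all activities."""

    n_deposition: float = 15.0  # kg N ha^-1 yr^-1 atmospheric deposition
    manure_recovery: float = 0.6  # fraction of excreted N available to crops
    fertilizer_co2e_per_kg_n: float = 6.0  # manufacture burden, kg CO2e per kg N
    rotation_max_share: dict[str, float] = field(
        default_factory=lambda: {
            "cereals": 0.6, "roots": 0.3, "legumes": 0.5, "breaks": 0.3, "forage": 1.0,
        }
    )
    caps_apply_to_conventional: bool = True
    cross_farm_manure_transfer: bool = False
    organic_price_multiplier: float = 1.0


@dataclass
class Economy:
    """The full study system: land, activities, demand and factor tables."""

    land_classes: list[LandClass]
    farm_types: list[FarmType]
    crop_activities: list[CropActivity]
    livestock_activities: list[LivestockActivity]
    demand: dict[str, float]  # commodity -> t yr^-1
    import_origins: dict[str, dict[str, float]] = field(default_factory=dict)
    transport_coefficients: dict[str, float] = field(default_factory=dict)
    luc_factors: dict[str, float] = field(default_factory=dict)
    coc_factors: dict[str, float] = field(default_factory=dict)
    overseas_yields: dict[str, dict[str, float]] = field(default_factory=dict)
    params: EconomyParams = field(default_factory=EconomyParams)

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on the first breach."""
        keys = [lc.key for lc in self.land_classes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate land classes")
        class_keys = set(keys)
        for ft in self.farm_types:
            unknown = set(ft.land_by_class) - class_keys
            if unknown:
                raise ValueError(f"farm type {ft.name!r} references unknown classes {unknown}")
            for key, area in ft.land_by_class.items():
                if area < 0:
                    raise ValueError(f"farm type {ft.name!r}: negative area in {key}")
        for commodity, shares in self.import_origins.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"import origin shares for {commodity!r} sum to {total}, not 1"
                )
        for name, table in (
            ("transport_coefficients", self.transport_coefficients),
            ("luc_factors", self.luc_factors),
            ("coc_factors", self.coc_factors),
        ):
            for k, v in table.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] is negative")
        for commodity, t in self.demand.items():
            if t < 0:
                raise ValueError(f"negative demand for {commodity!r}")

    def crops_by_use(self, use: str) -> list[CropActivity]:
        return [c for c in self.crop_activities if c.use == use]

    @property
    def food_commodities(self) -> list[str]:
        return [c.commodity for c in self.crops_by_use("food")] + [
            l.species for l in self.livestock_activities
        ]

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path: str | Path, manifest: dict | None = None) -> None:
        """Serialise to a directory of CSV tables plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [dataclasses.asdict(lc) for lc in self.land_classes]
        ).to_csv(path / "land_classes.csv", index=False)
        pd.DataFrame(
            [
                {"farm_type": ft.name, "class_key": k, "hectares": v}
                for ft in self.farm_types
                for k, v in ft.land_by_class.items()
            ]
        ).to_csv(path / "farm_types.csv", index=False)
        crop_rows = []
        for c in self.crop_activities:
            for system, by_class in c.yield_by_class.items():
                for key, y in by_class.items():
                    crop_rows.append(
                        {
                            "commodity": c.commodity, "system": system, "class_key": key,
                            "yield_t_ha": y, "me_coefficient": c.me_coefficient,
                            "n_offtake": c.n_offtake, "n_fixation": c.n_fixation,
                            "rotation_group": c.rotation_group,
                            "baseline_supply": c.baseline_supply, "use": c.use,
                            "energy_co2_per_ha": c.energy_co2_per_ha.get(system, 0.0),
                            "price": c.price, "is_legume": c.is_legume,
                        }
                    )
        pd.DataFrame(crop_rows).to_csv(path / "crops.csv", index=False)
        ls_rows = []
        for l in self.livestock_activities:
            for system in SYSTEMS:
                ls_rows.append(
                    {
                        "species": l.species, "system": system,
                        "me_feed_demand": l.me_feed_demand,
                        "forage_share": l.diet_shares[0],
                        "concentrate_share": l.diet_shares[1],
                        "product_yield": l.product_yield.get(system, 0.0),
                        "product_me": l.product_me, "n_excretion": l.n_excretion,
                        "mortality": l.mortality, "stocking_min": l.stocking_min,
                        "stocking_max": l.stocking_max,
                        "baseline_supply": l.baseline_supply,
                        "dry_matter_intake": l.dry_matter_intake,
                        "liveweight": l.liveweight, "milk_yield": l.milk_yield,
                        "energy_co2_per_head": l.energy_co2_per_head.get(system, 0.0),
                        "manure_ch4_per_head": l.manure_ch4_per_head, "price": l.price,
                    }
                )
        pd.DataFrame(ls_rows).to_csv(path / "livestock.csv", index=False)
        pd.DataFrame(
            [{"commodity": k, "demand_t": v} for k, v in sorted(self.demand.items())]
        ).to_csv(path / "demand.csv", index=False)
        trade_rows = []
        for commodity, shares in sorted(self.import_origins.items()):
            for origin, share in sorted(shares.items()):
                trade_rows.append(
                    {
                        "commodity": commodity, "origin": origin, "share": share,
                        "transport_kgco2e_per_t": self.transport_coefficients.get(origin, 0.0),
                        "luc_tco2e_per_ha": self.luc_factors.get(origin, 0.0),
                        "coc_kgco2e_per_kg": self.coc_factors.get(commodity, 0.0),
                        "overseas_yield_t_ha": self.overseas_yields.get(commodity, {}).get(origin, 0.0),
                    }
                )
        pd.DataFrame(trade_rows).to_csv(path / "trade_factors.csv", index=False)
        payload = {"params": dataclasses.asdict(self.params)}
        if manifest:
            payload.update(manifest)
        (path / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "Economy":
        path = Path(path)
        land = pd.read_csv(path / "land_classes.csv")
        land_classes = [
            LandClass(r.soil_class, r.rainfall_class, r.area) for r in land.itertuples()
        ]
        ftab = pd.read_csv(path / "farm_types.csv")
        farm_types = [
            FarmType(name, dict(zip(g.class_key, g.hectares)))
            for name, g in ftab.groupby("farm_type", sort=False)
        ]
        crops_df = pd.read_csv(path / "crops.csv")
        crops = []
        for commodity, g in crops_df.groupby("commodity", sort=False):
            first = g.iloc[0]
            yields: dict[str, dict[str, float]] = {}
            energy: dict[str, float] = {}
            for system, gs in g.groupby("system"):
                yields[system] = dict(zip(gs.class_key, gs.yield_t_ha))
                energy[system] = float(gs.energy_co2_per_ha.iloc[0])
            crops.append(
                CropActivity(
                    commodity=commodity, yield_by_class=yields,
                    me_coefficient=float(first.me_coefficient),
                    n_offtake=float(first.n_offtake),
                    n_fixation=float(first.n_fixation),
                    rotation_group=str(first.rotation_group),
                    baseline_supply=float(first.baseline_supply),
                    use=str(first.use), energy_co2_per_ha=energy,
                    price=float(first.price), is_legume=bool(first.is_legume),
                )
            )
        ldf = pd.read_csv(path / "livestock.csv")
        livestock = []
        for species, g in ldf.groupby("species", sort=False):
            first = g.iloc[0]
            livestock.append(
                LivestockActivity(
                    species=species,
                    me_feed_demand=float(first.me_feed_demand),
                    diet_shares=(float(first.forage_share), float(first.concentrate_share)),
                    product_yield={r.system: float(r.product_yield) for r in g.itertuples()},
                    product_me=float(first.product_me),
                    n_excretion=float(first.n_excretion),
                    mortality=float(first.mortality),
                    stocking_min=float(first.stocking_min),
                    stocking_max=float(first.stocking_max),
                    baseline_supply=float(first.baseline_supply),
                    dry_matter_intake=float(first.dry_matter_intake),
                    liveweight=float(first.liveweight),
                    milk_yield=float(first.milk_yield),
                    energy_co2_per_head={r.system: float(r.energy_co2_per_head) for r in g.itertuples()},
                    manure_ch4_per_head=float(first.manure_ch4_per_head),
                    price=float(first.price),
                )
            )
        demand_df = pd.read_csv(path / "demand.csv")
        demand = dict(zip(demand_df.commodity, demand_df.demand_t))
        trade = pd.read_csv(path / "trade_factors.csv")
        import_origins: dict[str, dict[str, float]] = {}
        transport: dict[str, float] = {}
        luc: dict[str, float] = {}
        coc: dict[str, float] = {}
        overseas: dict[str, dict[str, float]] = {}
        for r in trade.itertuples():
            import_origins.setdefault(r.commodity, {})[r.origin] = float(r.share)
            transport[r.origin] = float(r.transport_kgco2e_per_t)
            luc[r.origin] = float(r.luc_tco2e_per_ha)
            coc[r.commodity] = float(r.coc_kgco2e_per_kg)
            overseas.setdefault(r.commodity, {})[r.origin] = float(r.overseas_yield_t_ha)
        manifest = json.loads((path / "manifest.json").read_text())
        params = EconomyParams(**manifest.get("params", {}))
        economy = cls(
            land_classes=land_classes, farm_types=farm_types,
            crop_activities=crops, livestock_activities=livestock,
            demand=demand, import_origins=import_origins,
            transport_coefficients=transport, luc_factors=luc,
            coc_factors=coc, overseas_yields=overseas, params=params,
        )
        economy.validate()
        return economy


# ---------------------------------------------------------------- generator


@dataclass(frozen=True)
class EconomySpec:
    """Recipe for a random economy.

    Counts select the first entries of the standard name pools; coefficient
    ranges are (low, high) bounds for uniform draws.  Organic yields are a
    drawn per-crop fraction of conventional yields (the organic yield gap);
    demand is a fixed fraction of the conventional-optimum production so that
    shortfalls under organic management are structural, not accidental.
    """

    n_farm_types: int = 2
    n_food_crops: int = 3
    n_livestock: int = 2
    soil_classes: tuple[str, ...] = SOIL_CLASSES
    rainfall_classes: tuple[str, ...] = RAINFALL_CLASSES
    total_area: float = 100_000.0  # ha
    yield_range: tuple[float, float] = (4.0, 10.0)  # t/ha conventional
    me_range: tuple[float, float] = (3.0, 15.0)  # GJ/t
    organic_yield_ratio_range: tuple[float, float] = (0.55, 0.8)
    n_offtake_range: tuple[float, float] = (8.0, 22.0)  # kg N/t
    n_fixation_range: tuple[float, float] = (150.0, 250.0)  # kg N/ha
    demand_fraction: float = 1.0  # of conventional-optimum production
    farm_type_names: tuple[str, ...] = DEFAULT_FARM_TYPE_NAMES
    origins: tuple[str, ...] = ("europe", "americas", "oceania")

    def __post_init__(self) -> None:
        if self.n_farm_types < 1 or self.n_food_crops < 1 or self.n_livestock < 0:
            raise ValueError("counts must be positive (livestock may be 0)")
        if self.n_farm_types > len(self.farm_type_names):
            raise ValueError("not enough farm type names for n_farm_types")
        if self.n_food_crops > len(_FOOD_CROP_POOL):
            raise ValueError(f"at most {len(_FOOD_CROP_POOL)} food crops supported")
        if self.n_livestock > len(_LIVESTOCK_POOL):
            raise ValueError(f"at most {len(_LIVESTOCK_POOL)} livestock supported")


def _class_yield_multipliers(rng: np.random.Generator, keys: list[str]) -> dict[str, float]:
    return {k: float(rng.uniform(0.8, 1.2)) for k in keys}


def generate_economy(spec: EconomySpec, seed: int) -> Economy:
    """Generate a feasible random economy; (spec, seed) fully determine it.

    The conventional LP for the generated system is solved internally to set
    the baseline supply (hence the 150% caps) and the demand table; if either
    system's LP is infeasible a diagnostic naming the violated resource rows
    is raised.
    """
    from . import land_use_optimizer as luo  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)

    class_keys = [
        f"{s}:{r}" for s in spec.soil_classes for r in spec.rainfall_classes
    ]
    shares = rng.dirichlet(np.ones(len(class_keys)))
    land_classes = []
    for key, share in zip(class_keys, shares):
        soil, rain = key.split(":")
        land_classes.append(LandClass(soil, rain, float(share * spec.total_area)))

    farm_names = list(spec.farm_type_names[: spec.n_farm_types])
    farm_types = []
    ft_shares = rng.dirichlet(np.ones(spec.n_farm_types), size=len(class_keys))
    for i, name in enumerate(farm_names):
        land = {
            lc.key: float(lc.area * ft_shares[j][i])
            for j, lc in enumerate(land_classes)
        }
        farm_types.append(FarmType(name, land))

    crops: list[CropActivity] = []
    for name in _FOOD_CROP_POOL[: spec.n_food_crops]:
        base = float(rng.uniform(*spec.yield_range))
        mult = _class_yield_multipliers(rng, class_keys)
        organic_ratio = float(rng.uniform(*spec.organic_yield_ratio_range))
        is_legume = name in _LEGUME_FOOD_CROPS
        crops.append(
            CropActivity(
                commodity=name,
                yield_by_class={
                    CONVENTIONAL: {k: base * m for k, m in mult.items()},
                    ORGANIC: {k: base * m * organic_ratio for k, m in mult.items()},
                },
                me_coefficient=float(rng.uniform(*spec.me_range)),
                n_offtake=0.0 if is_legume else float(rng.uniform(*spec.n_offtake_range)),
                n_fixation=float(rng.uniform(*spec.n_fixation_range)) if is_legume else 0.0,
                rotation_group=_ROTATION_GROUP[name],
                use="food",
                energy_co2_per_ha={
                    CONVENTIONAL: float(rng.uniform(200, 600)),
                    ORGANIC: float(rng.uniform(250, 700)),
                },
                price=float(rng.uniform(0.5, 2.0)),
                is_legume=is_legume,
            )
        )

    # always-present on-farm feed crops: a N-fixing grass-clover ley and,
    # if there is livestock, a concentrate feed grain
    ley_base = float(rng.uniform(6.0, 10.0))
    ley_mult = _class_yield_multipliers(rng, class_keys)
    crops.append(
        CropActivity(
            commodity="grass clover ley",
            yield_by_class={
                CONVENTIONAL: {k: ley_base * m for k, m in ley_mult.items()},
                ORGANIC: {k: ley_base * m * 0.9 for k, m in ley_mult.items()},
            },
            me_coefficient=float(rng.uniform(8.0, 11.0)),
            n_offtake=0.0,
            n_fixation=float(rng.uniform(*spec.n_fixation_range)),
            rotation_group="forage",
            use="forage",
            energy_co2_per_ha={CONVENTIONAL: 100.0, ORGANIC: 100.0},
            is_legume=True,
        )
    )
    if spec.n_livestock > 0:
        fg_base = float(rng.uniform(*spec.yield_range))
        fg_mult = _class_yield_multipliers(rng, class_keys)
        fg_ratio = float(rng.uniform(*spec.organic_yield_ratio_range))
        crops.append(
            CropActivity(
                commodity="feed grain",
                yield_by_class={
                    CONVENTIONAL: {k: fg_base * m for k, m in fg_mult.items()},
                    ORGANIC: {k: fg_base * m * fg_ratio for k, m in fg_mult.items()},
                },
                me_coefficient=float(rng.uniform(10.0, 14.0)),
                n_offtake=float(rng.uniform(*spec.n_offtake_range)),
                rotation_group="cereals",
                use="feed_grain",
                energy_co2_per_ha={
                    CONVENTIONAL: float(rng.uniform(200, 600)),
                    ORGANIC: float(rng.uniform(250, 700)),
                },
            )
        )

    livestock: list[LivestockActivity] = []
    for name in _LIVESTOCK_POOL[: spec.n_livestock]:
        ruminant = name in ("dairy", "beef", "sheep")
        forage_share = float(rng.uniform(0.55, 0.9)) if ruminant else float(rng.uniform(0.0, 0.15))
        conv_yield = float(rng.uniform(0.1, 6.0) if name == "dairy" else rng.uniform(0.05, 0.5))
        organic_ratio = float(rng.uniform(0.7, 0.95))
        livestock.append(
            LivestockActivity(
                species=name,
                me_feed_demand=float(rng.uniform(20.0, 60.0)),
                diet_shares=(forage_share, 1.0 - forage_share),
                product_yield={CONVENTIONAL: conv_yield, ORGANIC: conv_yield * organic_ratio},
                product_me=float(rng.uniform(5.0, 15.0)),
                n_excretion=float(rng.uniform(40.0, 120.0)),
                mortality=float(rng.uniform(0.02, 0.08)),
                stocking_min=0.0,
                stocking_max=float(rng.uniform(2.0, 6.0)),
                dry_matter_intake=float(rng.uniform(2000.0, 7000.0)),
                liveweight=float(rng.uniform(40.0, 650.0)),
                milk_yield=conv_yield if name == "dairy" else 0.0,
                energy_co2_per_head={
                    CONVENTIONAL: float(rng.uniform(50.0, 300.0)),
                    ORGANIC: float(rng.uniform(40.0, 280.0)),
                },
                manure_ch4_per_head=float(rng.uniform(2.0, 30.0)),
                price=float(rng.uniform(0.5, 3.0)),
            )
        )

    origins = list(spec.origins)
    transport = {o: float(rng.uniform(50.0, 300.0)) for o in origins}
    luc_factors = {o: float(rng.uniform(2.0, 15.0)) for o in origins}

    economy = Economy(
        land_classes=land_classes,
        farm_types=farm_types,
        crop_activities=crops,
        livestock_activities=livestock,
        demand={},
        transport_coefficients=transport,
        luc_factors=luc_factors,
        params=EconomyParams(),
    )

    # baseline supply and demand come from the unconstrained conventional optimum
    problem = luo.build_lp(economy, CONVENTIONAL)
    solution = luo.solve_lp(problem)
    if solution.status != "optimal":
        raise ValueError(
            "infeasible spec: conventional LP is "
            f"{solution.status}; violated resources: {solution.binding_constraints}"
        )
    for c in economy.crops_by_use("food"):
        c.baseline_supply = max(solution.production.get(c.commodity, 0.0), 1.0)
    for l in economy.livestock_activities:
        l.baseline_supply = max(solution.production.get(l.species, 0.0), 1.0)
    economy.demand = {
        commodity: spec.demand_fraction * max(solution.production.get(commodity, 0.0), 0.0)
        for commodity in economy.food_commodities
    }

    share_draws = rng.dirichlet(np.ones(len(origins)), size=len(economy.food_commodities))
    for i, commodity in enumerate(economy.food_commodities):
        economy.import_origins[commodity] = {
            o: float(s) for o, s in zip(origins, share_draws[i])
        }
        economy.coc_factors[commodity] = float(rng.uniform(1.0, 5.0))
        economy.overseas_yields[commodity] = {
            o: float(rng.uniform(2.0, 8.0)) for o in origins
        }
    # feed crops carry their own COC rows, separate from human-food uses
    for c in economy.crop_activities:
        if c.use != "food":
            economy.coc_factors[c.commodity] = float(rng.uniform(0.5, 3.0))
            economy.overseas_yields[c.commodity] = {
                o: float(rng.uniform(2.0, 8.0)) for o in origins
            }
            economy.import_origins[c.commodity] = {
                o: float(s) for o, s in zip(origins, rng.dirichlet(np.ones(len(origins))))
            }

    economy.validate()

    organic_solution = luo.solve_lp(luo.build_lp(economy, ORGANIC))
    if organic_solution.status != "optimal":
        raise ValueError(
            "infeasible spec: organic LP is "
            f"{organic_solution.status}; violated resources: {organic_solution.binding_constraints}"
        )
    return economy


# --------------------------------------------------- known-optimum fixtures


def _one_class_economy(
    crops: list[CropActivity],
    livestock: list[LivestockActivity],
    demand: Mapping[str, float],
    area: float = 100.0,
    n_deposition: float = 0.0,
) -> Economy:
    lc = LandClass("medium", "medium", area)
    ft = FarmType("specialist cropping", {lc.key: area})
    econ = Economy(
        land_classes=[lc],
        farm_types=[ft],
        crop_activities=crops,
        livestock_activities=livestock,
        demand=dict(demand),
        params=EconomyParams(n_deposition=n_deposition),
    )
    econ.validate()
    return econ


def generate_known_optimum_case(kind: str):
    """Return (economy, system, expected LandUseSolution) for an archetype.

    ``single_crop``: 100 ha, one crop — everything planted, objective
    100*y*me.  ``two_crop_cap``: the higher-ME crop hits its 150% cap, the
    remainder goes to the second crop.  ``n_limited``: a legume must be grown
    to supply the N a cereal removes; the split follows from the binding N
    balance.  Expected solutions are computed here in closed form.
    """
    from .land_use_optimizer import LandUseSolution  # deferred import cycle

    both = {CONVENTIONAL: None, ORGANIC: None}

    if kind == "single_crop":
        y, me = 8.0, 13.0
        crop = CropActivity(
            commodity="wheat",
            yield_by_class={s: {"medium:medium": y} for s in SYSTEMS},
            me_coefficient=me, n_offtake=0.0, rotation_group="cereals",
            baseline_supply=float("inf"),
        )
        econ = _one_class_economy([crop], [], {"wheat": 100.0 * y})
        econ.params.rotation_max_share = {"cereals": 1.0}
        expected = LandUseSolution(
            activity_levels={("crop", "specialist cropping", "wheat", "medium:medium"): 100.0},
            production={"wheat": 100.0 * y},
            objective=100.0 * y * me,
            binding_constraints=["land:specialist cropping:medium:medium"],
            status="optimal",
        )
        return econ, CONVENTIONAL, expected

    if kind == "two_crop_cap":
        # crop A at 120 GJ/ha is preferred but capped at 1.5 x 400 t = 600 t
        y_a, me_a, base_a = 10.0, 12.0, 400.0
        y_b, me_b = 8.0, 10.0
        crop_a = CropActivity(
            commodity="potatoes",
            yield_by_class={s: {"medium:medium": y_a} for s in SYSTEMS},
            me_coefficient=me_a, n_offtake=0.0, rotation_group="roots",
            baseline_supply=base_a,
        )
        crop_b = CropActivity(
            commodity="wheat",
            yield_by_class={s: {"medium:medium": y_b} for s in SYSTEMS},
            me_coefficient=me_b, n_offtake=0.0, rotation_group="cereals",
            baseline_supply=float("inf"),
        )
        econ = _one_class_economy(
            [crop_a, crop_b], [], {"potatoes": base_a, "wheat": 40.0 * y_b}
        )
        econ.params.rotation_max_share = {"roots": 1.0, "cereals": 1.0}
        area_a = CAP_MULTIPLIER * base_a / y_a  # 60 ha
        area_b = 100.0 - area_a
        expected = LandUseSolution(
            activity_levels={
                ("crop", "specialist cropping", "potatoes", "medium:medium"): area_a,
                ("crop", "specialist cropping", "wheat", "medium:medium"): area_b,
            },
            production={"potatoes": CAP_MULTIPLIER * base_a, "wheat": area_b * y_b},
            objective=CAP_MULTIPLIER * base_a * me_a + area_b * y_b * me_b,
            binding_constraints=["cap:potatoes", "land:specialist cropping:medium:medium"],
            status="optimal",
        )
        return econ, CONVENTIONAL, expected

    if kind == "n_limited":
        # cereal ME/ha (104) beats legume (60) but removes 160 kg N/ha which
        # only the legume (200 kg N/ha fixed) can supply under organic rules
        y_c, me_c, n_off = 8.0, 13.0, 20.0
        y_l, me_l, n_fix = 5.0, 12.0, 200.0
        cereal = CropActivity(
            commodity="wheat",
            yield_by_class={s: {"medium:medium": y_c} for s in SYSTEMS},
            me_coefficient=me_c, n_offtake=n_off, rotation_group="cereals",
            baseline_supply=float("inf"),
        )
        legume = CropActivity(
            commodity="field beans",
            yield_by_class={s: {"medium:medium": y_l} for s in SYSTEMS},
            me_coefficient=me_l, n_offtake=0.0, n_fixation=n_fix,
            rotation_group="legumes", baseline_supply=float("inf"), is_legume=True,
        )
        econ = _one_class_economy(
            [cereal, legume], [], {"wheat": 400.0, "field beans": 200.0},
            n_deposition=0.0,
        )
        econ.params.rotation_max_share = {"cereals": 1.0, "legumes": 1.0}
        # binding N row: n_fix*a = n_off*y_c*(100 - a)
        demand_per_ha = n_off * y_c
        a_legume = 100.0 * demand_per_ha / (n_fix + demand_per_ha)
        a_cereal = 100.0 - a_legume
        expected = LandUseSolution(
            activity_levels={
                ("crop", "specialist cropping", "field beans", "medium:medium"): a_legume,
                ("crop", "specialist cropping", "wheat", "medium:medium"): a_cereal,
            },
            production={"field beans": a_legume * y_l, "wheat": a_cereal * y_c},
            objective=a_legume * y_l * me_l + a_cereal * y_c * me_c,
            binding_constraints=[
                "land:specialist cropping:medium:medium",
                "nitrogen:specialist cropping",
            ],
            status="optimal",
        )
        return econ, ORGANIC, expected

    raise ValueError(f"unknown archetype {kind!r}")
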