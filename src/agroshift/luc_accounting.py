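"""Scenario accounting for overseas land-use change, soil-carbon offsets and
carbon opportunity cost.

A national net GHG budget under full organic conversion is

    total = direct + transport + LUC - sequestration (+ COC if included)

where LUC emissions arise from converting overseas grassland to cropland to
grow the imports that replace domestic shortfalls, sequestration credits soil
C gains on organically managed arable land at home and overseas, and the
carbon opportunity cost (COC) prices the forest regrowth foregone by keeping
the additional land in agriculture.  Three stylised scenarios bracket the
outcome: High (all LUC from grassland, no sequestration), Medium (50% from
grassland, moderate 0.07 Mg C ha^-1 yr^-1 sequestration) and Low (25% from
grassland, high 0.18 Mg C ha^-1 yr^-1 sequestration).  Woodland is never
converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .soil_carbon import CO2_PER_C

__all__ = [
    "ScenarioSpec",
    "HIGH",
    "MEDIUM",
    "LOW",
    "SCENARIOS",
    "BudgetRow",
    "luc_emissions",
    "sequestration_offset",
    "carbon_opportunity_cost",
    "net_budget",
]

T_PER_MT = 1e6


@dataclass(frozen=True)
class ScenarioSpec:
    """One LUC / sequestration scenario.

    grassland_fraction: share of additional overseas arable area converted
    from grassland (the rest comes from existing cropland, at no LUC cost).
    seq_rate: flat soil C sequestration rate (Mg C ha^-1 yr^-1) applied to
    eligible arable land at home and overseas.
    """

    name: str
    grassland_fraction: float
    seq_rate: float
    include_coc: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.grassland_fraction <= 1.0:
            raise ValueError("grassland_fraction must be in [0, 1]")
        if self.seq_rate < 0:
            raise ValueError("seq_rate must be >= 0")


HIGH = ScenarioSpec("High", grassland_fraction=1.0, seq_rate=0.0)
MEDIUM = ScenarioSpec("Medium", grassland_fraction=0.5, seq_rate=0.07)
LOW = ScenarioSpec("Low", grassland_fraction=0.25, seq_rate=0.18)
SCENARIOS = {"High": HIGH, "Medium": MEDIUM, "Low": LOW}


@dataclass
class BudgetRow:
    """National totals for one scenario (all in Mt CO2e yr^-1).

    components: direct, transport, luc, sequestration (negative), coc.
    Gas fractions are percentages of the positive emission total.
    """

    scenario: str
    total: float
    sd: float = 0.0
    components: dict[str, float] = field(default_factory=dict)
    gas_fractions: dict[str, float] = field(default_factory=dict)
    pct_change_vs_baseline: float | None = None
    significant: bool | None = None


def luc_emissions(
    additional_area: Mapping[str, float],
    scenario: ScenarioSpec,
    luc_factors: Mapping[str, float],
) -> float:
    """Annual LUC emissions, in t CO2e yr^-1.

    Sum over origins of additional area (ha) x grassland_fraction x the
    origin's grassland-conversion emission factor (t CO2e ha^-1 yr^-1).
    Origins with zero area need no factor; any origin with area must have one.
    """
    total = 0.0
    for origin, area in additional_area.items():
        if area < 0:
            raise ValueError(f"negative additional area for origin {origin!r}")
        if area == 0:
            continue
        if origin not in luc_factors:
            raise KeyError(f"no LUC emission factor for origin {origin!r}")
        factor = luc_factors[origin]
        if factor < 0:
            raise ValueError(f"negative LUC factor for origin {origin!r}")
        total += area * scenario.grassland_fraction * factor
    return total


def sequestration_offset(
    eligible_arable_area_home: float,
    eligible_arable_area_overseas: float,
    scenario: ScenarioSpec,
) -> float:
    """Soil C sequestration credit, in Mt CO2e yr^-1 (<= 0).

    -(home + overseas eligible area) x seq_rate x 44/12.  Eligible area is
    organically managed arable plus rotational grass; permanent pasture is at
    steady state and contributes nothing.  Zero under the High scenario.
    """
    if eligible_arable_area_home < 0 or eligible_arable_area_overseas < 0:
        raise ValueError("areas must be >= 0")
    area = eligible_arable_area_home + eligible_arable_area_overseas
    return -(area * scenario.seq_rate * CO2_PER_C) / T_PER_MT


def carbon_opportunity_cost(
    additional_imports: Mapping[str, float],
    coc_factors: Mapping[str, float],
) -> float:
    """Carbon opportunity cost of additional imports, in t CO2e yr^-1.

    Sum of additional fresh-weight imports (t) x the commodity's COC factor
    (kg CO2e per kg fresh weight, numerically equal to t CO2e per t).  Added
    on top of scenario LUC emissions, never in place of them.  Human-food and
    feed uses of a crop carry separate factor rows upstream; by the time mass
    reaches here each key is a single (commodity, use) flow.
    """
    total = 0.0
    for commodity, mass in additional_imports.items():
        if mass < 0:
            raise ValueError(f"negative additional imports for {commodity!r}")
        if mass == 0:
            continue
        if commodity not in coc_factors:
            raise KeyError(f"no COC factor for commodity {commodity!r}")
        total += mass * coc_factors[commodity]
    return total


def net_budget(
    direct: float,
    transport: float,
    luc: float,
    seq: float,
    baseline: float,
    coc: float = 0.0,
    include_coc: bool = False,
) -> tuple[float, float]:
    """Net national total (Mt CO2e yr^-1) and integer % change vs baseline.

    total = direct + transport + luc + seq (+ coc if included); seq enters as
    a negative credit.  Percent change is 100*(total - baseline)/baseline,
    reported to the nearest integer as conventionally printed.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    total = direct + transport + luc + seq
    if include_coc:
        total += coc
    pct = round(100.0 * (total - baseline) / baseline)
    return total, pct
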