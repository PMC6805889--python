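"""Balancing domestic production against demand: imports, exports, transport
emissions and the overseas land footprint of imports.

Domestic consumption takes priority: when production falls short of demand the
gap is met entirely by imports and nothing is exported; a surplus is exported
and its production burdens are credited back to the national total.  Imports
are split across historic origins by fixed shares, each origin carrying its
own transport emission coefficient and crop yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TradeFlow",
    "balance_commodity",
    "make_trade_flow",
    "import_transport_emissions",
    "overseas_land_requirement",
    "trade_flows_frame",
]


@dataclass
class TradeFlow:
    """Import/export position for one commodity (t fresh weight yr^-1)."""

    commodity: str
    production: float
    demand: float
    imports: float
    exports: float
    origin_allocation: dict[str, float] = field(default_factory=dict)
    transport_emissions: float = 0.0  # kg CO2e
    overseas_area: dict[str, float] = field(default_factory=dict)  # ha by origin

    def __post_init__(self) -> None:
        if self.imports < 0 or self.exports < 0:
            raise ValueError("imports and exports must be >= 0")
        if self.imports > 0 and self.exports > 0:
            raise ValueError("a commodity cannot be imported and exported at once")
        alloc = sum(self.origin_allocation.values())
        if self.origin_allocation and abs(alloc - self.imports) > 1e-6 * max(1.0, self.imports):
            raise ValueError("origin allocation must sum to imports")


def balance_commodity(production: float, demand: float) -> tuple[float, float]:
    """(imports, exports) closing the gap between production and demand.

    Shortfalls are imported, surpluses exported, never both.
    """
    if production < 0 or demand < 0:
        raise ValueError("production and demand must be >= 0")
    if production < demand:
        return demand - production, 0.0
    return 0.0, production - demand


def make_trade_flow(
    commodity: str,
    production: float,
    demand: float,
    origin_shares: Mapping[str, float] | None = None,
) -> TradeFlow:
    """Balance one commodity and allocate any imports across origins."""
    imports, exports = balance_commodity(production, demand)
    allocation: dict[str, float] = {}
    if imports > 0:
        shares = dict(origin_shares or {"rest_of_world": 1.0})
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin shares for {commodity!r} sum to {total}, not 1")
        allocation = {o: imports * s for o, s in shares.items() if s > 0}
    return TradeFlow(
        commodity=commodity,
        production=production,
        demand=demand,
        imports=imports,
        exports=exports,
        origin_allocation=allocation,
    )


def import_transport_emissions(
    flow: TradeFlow, coefficients: Mapping[str, float]
) -> float:
    """Transport emissions of a flow's imports, kg CO2e.

    Sum over origins of tonnage x the origin's coefficient (kg CO2e t^-1).
    The result is also stored on the flow.  Export burden credits are handled
    in budget assembly, not here.
    """
    total = 0.0
    for origin, tonnage in flow.origin_allocation.items():
        if tonnage == 0:
            continue
        if origin not in coefficients:
            raise KeyError(
                f"no transport coefficient for origin {origin!r} (commodity {flow.commodity!r})"
            )
        total += tonnage * coefficients[origin]
    flow.transport_emissions = total
    return total


def overseas_land_requirement(
    flows: Sequence[TradeFlow],
    overseas_yields: Mapping[str, Mapping[str, float]],
    baseline_overseas_area: Mapping[tuple[str, str], float] | None = None,
) -> tuple[float, float]:
    """Total and additional overseas area (ha) needed to grow the imports.

    Per (commodity, origin): area = imports / yield; the additional area is
    the excess over the conventional-baseline area for that same pair,
    floored at zero pair by pair — one commodity's spare baseline land never
    offsets another's deficit.  Areas are stored per origin on each flow.
    """
    baseline = dict(baseline_overseas_area or {})
    total = 0.0
    additional = 0.0
    for flow in flows:
        flow.overseas_area = {}
        for origin, tonnage in flow.origin_allocation.items():
            if tonnage == 0:
                continue
            y = overseas_yields.get(flow.commodity, {}).get(origin, 0.0)
            if y <= 0:
                raise ValueError(
                    f"no positive overseas yield for {flow.commodity!r} from {origin!r}"
                )
            area = tonnage / y
            flow.overseas_area[origin] = area
            total += area
            additional += max(area - baseline.get((flow.commodity, origin), 0.0), 0.0)
    return total, additional


def trade_flows_frame(flows: Sequence[TradeFlow]) -> pd.DataFrame:
    """Long-format table of flows (one row per commodity x origin)."""
    rows = []
    for f in flows:
        origins = f.origin_allocation or {"": 0.0}
        for origin, tonnage in origins.items():
            rows.append(
                {
                    "commodity": f.commodity,
                    "production": f.production,
                    "demand": f.demand,
                    "imports": f.imports,
                    "exports": f.exports,
                    "origin": origin,
                    "tonnage": tonnage,
                    "transport_kgco2e": f.transport_emissions,
                    "overseas_ha": f.overseas_area.get(origin, 0.0),
                }
            )
    return pd.DataFrame(rows)
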