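# Methods

## Scope and model chain

agroshift implements a national assessment of converting agriculture to
organic methods as a chain of five models: a land-use LP, a farm-gate LCA,
a trade balance, a single-pool soil-carbon model with land-use-change (LUC)
scenario accounting, and Monte-Carlo uncertainty propagation. The package
runs entirely on synthetic economies with known structure; it makes no
attempt to reproduce the absolute magnitudes of any real country's
agriculture, which would require survey-derived coefficient tables.

## The land-use LP

Objective: total metabolisable energy (ME) of food production, in GJ yr⁻¹.
ME is the objective currency because food-energy supply is the binding
nutritional constraint at population scale. Activities are crop areas per
(farm type, commodity, soil × rainfall class) and livestock head counts per
(farm type, species). All constraints are linear and of the form
*Rx* ≤ **b** with *x* ≥ 0:

- **Land** — one row per farm type × land class; farm-type land is fixed
  (conversion does not move farm boundaries).
- **Rotation** — per farm type, each crop group (cereals, roots, legumes,
  breaks) may occupy at most a configurable share of the farm
  (defaults 0.6/0.3/0.5/0.3); shares of 1 generate no row.
- **Output caps** — national rows at 150% of baseline supply per
  commodity, representing limits on what the market can absorb. Caps apply
  to both systems by default (`EconomyParams.caps_apply_to_conventional`);
  whether a conventional run should be capped is genuinely open, and since
  the generator sets caps at 1.5× the conventional optimum the flag does
  not change conventional results under defaults.
- **Nitrogen** — one balance row per farm type (offtake ≤ fixation +
  atmospheric deposition + recycled manure + manufactured fertiliser).
  Granularity is per farm type, not per land class, because rotational N
  budgets operate at rotation level. Under conventional rules an unbounded
  zero-cost fertiliser-purchase variable relaxes the row; under organic
  rules the variable is absent and legumes/leys are the only scalable N
  source — this single switch produces the organic yield-system behaviour
  (leys displacing cash crops). Manure N is credited within the farm type
  that generates it; cross-farm-type transfer is off by default because no
  transfer rule is part of the model.
- **Feed** — per farm type, forage ME and concentrate ME supplied by
  on-farm forage/feed-grain crops must cover the herd's diet-share-weighted
  ME demand. Feed is not imported: livestock scale with what the land can
  grow.
- **Stocking** — head counts bounded by min/max densities per hectare of
  forage area.

Solver: `scipy.optimize.linprog` with HiGHS — deterministic, no randomised
presolve, feasibility ~1e-9. LP optima are vertex solutions and may be
non-unique; all downstream claims and tests therefore rest on the objective
value and aggregate production, never on individual activity levels.
Infeasibility is diagnosed by re-solving with elastic slacks (minimise total
violation) and reporting the rows that remain violated.

## Farm-gate LCA

Boundary: cradle to farm gate; on-farm processing energy is inside,
distribution and consumption outside. Per commodity and system the engine
sums:

- **CO₂** — field/housing energy (kg CO₂ ha⁻¹ or head⁻¹, activity
  coefficients) plus fertiliser manufacture at 6 kg CO₂e per kg N
  (conventional only). Manure system expansion is implemented by meeting
  crop N demand from manure before manufactured N, which is arithmetically
  the avoided-fertiliser credit; the standalone
  `manure_system_expansion` op exposes the credit explicitly.
- **N₂O** — IPCC-2006-style Tier 1: direct EF 0.01 of applied N; leaching
  fraction 0.30 (EF 0.0075), raised by 0.15 once for heavy soils and once
  for very-wet rainfall classes; volatilisation fractions 0.10
  (synthetic) / 0.20 (manure) with EF 0.010; ×44/28. All factors are
  configurable per `EmissionFactorSet`.
- **CH₄** — enteric: methane yield per kg dry-matter intake interpolated
  between concentrate (0.018) and forage (0.023 kg CH₄ per kg DM) with the
  diet's forage share, times multiplicative live-weight and milk-yield
  adjustments equal to 1 at the reference animal. The functional form keeps
  CH₄ exactly linear in intake and zero at zero intake, and reproduces the
  qualitative dependencies (more forage → more CH₄). Manure-management CH₄
  is a per-head coefficient.

Feed-crop burdens accumulate per farm type and are allocated to its
livestock in proportion to feed-energy demand — feed emissions belong to
the livestock sector, never the crop sector. Co-product burdens split by
economic value (mass × price, optional per-product organic price
differential, default multiplier 1.0). GWP-100: CH₄ 25, N₂O 298,
era-consistent with the IPCC-2006 factor basis; no 20-year mode.

## Trade and overseas land

Supply identity, exact by construction: production + imports − exports =
demand per commodity. Shortfalls are imported (domestic consumption takes
priority, so imports and exports never coexist); surpluses are exported and
their production burdens subtracted from the national total (after
co-product allocation). Imports are produced organically in origin regions
whose emission archetype defaults to the domestic organic profile
(conventional profile as fallback for commodities with no domestic organic
production). Overseas area = imports / origin yield; *additional* area is
the excess over the conventional baseline's requirement, floored at zero
per (commodity, origin) pair — no cross-commodity netting.

## Soil carbon

Single pool: d*C*/d*t* = *I* − *kC*; steady state *I*/*k*; closed-form
trajectory used as its own oracle against numerical integration. A land-use
transition is summarised by the flat rate ((*I* − *kC*₀) + 0)/2 — the mean
of the initial rate and the zero rate at the new steady state — applied as
a constant annual credit in budgets, with time-to-steady-state
(*C*\* − *C*₀)/rate reported as metadata. The reference rotational-grass
parameters (*I* = 2.54 Mg C ha⁻¹ yr⁻¹, *k* = 0.046 yr⁻¹, mean arable stock
43.2 Mg C ha⁻¹) give 0.28 Mg C ha⁻¹ yr⁻¹, area-weighted by 552 arable /
301 rotational-grass sites to 0.18. Note an internal inconsistency of the
printed reference values: *I*/*k* = 55.22 while the published steady state
is printed as 55.0 and the time-to-steady-state arithmetic uses 55.02. The
package treats printed values as exact inputs and does not resolve the
discrepancy; worked-example checks compare at printed precision (2 d.p.
rates, whole years) while full precision is kept internally. Chained
conversions follow the printed-precision convention (0.28 × 44/12 → 1.03),
since converting the unrounded 0.2764 would print 1.01. Permanent pasture
and rough grazing are at steady state and sequester nothing; organic-soil
classes and multi-pool (RothC-style) models are out of scope.

## Scenarios, COC and budgets

High/Medium/Low fix (grassland fraction of additional arable area,
sequestration rate): (1.0, 0), (0.5, 0.07), (0.25, 0.18 Mg C ha⁻¹ yr⁻¹).
LUC emissions = additional area × grassland fraction × per-origin factor
(t CO₂e ha⁻¹ yr⁻¹); woodland is never converted. Sequestration applies to
organically managed arable plus rotational-grass area at home and to the
overseas area serving imports. Carbon opportunity cost (COC) = additional
fresh-weight imports × per-commodity factors (kg CO₂e kg⁻¹, feed crops on
separate rows), added on top of — never instead of — the LUC scenarios,
and zero for the conventional baseline by definition. Both LUC losses and
sequestration gains are transition-period flows (a few decades) applied
here as flat annual rates. Budget total = direct + transport + LUC −
sequestration (+ COC); gas fractions are percentages of the net total with
transport, LUC and sequestration counted as CO₂.

## Uncertainty

Inputs carry symmetric triangular distributions with bounds at a stated
fraction *f* of the mean; the sd of such a triangular is mean·*f*/√6, so
*f* is a half-width, not a coefficient of variation — the two conventions
are kept distinct (half-widths drive sampling; true sd/mean CVs drive the
z test). Defaults: 10% per domestic crop commodity, 15% per livestock
commodity, 15% for imports en bloc (one shared multiplier — the
conservative, fully correlated reading), 10% transport, 17% LUC, 26% COC,
86% for the high sequestration rate and 24% for lower rates. A 15%
whole-solution land-area error is available through
`combine_components`' correlated blocks (one multiplier across all
LP-derived areas); the default scenario Monte Carlo treats LUC and
sequestration as independent components because they carry different
half-widths and blocks share one. n_sims defaults to 10,000; every stream
derives from the run seed via `SeedSequence`, so results are bit-identical
across reruns. Significance: *z* = |*m_A* − *m_B*| / √(sd_A² + sd_B²) with
sd = CV·m/100; the ×100 of the whole-number-CV formulation cancels under
this convention. *z* ≥ 1.96 marks 5% significance. Applying the test to
the printed reference Medium-scenario mean ± sd would yield *z* > 1.96
despite that comparison being reported as non-significant in the reference
table — the uncertainties behind that label evidently differ from the
printed sds — so the pipeline reports whatever its own simulation gives
and asserts nothing about Medium/Low labels. Similarly, the quoted "1.7
times" increase for Medium + COC is not reproducible from the printed
totals ((59.8 + 35.7)/49.3 ≈ 1.9); the pipeline reports the computed ratio
without asserting it.

## The synthetic-data generator

`generate_economy(spec, seed)` emulates the *structure* of the real inputs:
16 soil × rainfall land classes (Dirichlet-split areas over a default
100,000 ha), farm types drawn from the standard Robust Farm Type names
(the classification is nominally nine types but the canonical listing
names eight; the default set is those eight, configurable), food crops
from a named pool with per-class yield multipliers (0.8–1.2), a per-crop
organic yield ratio (0.55–0.8, matching field-scale organic yield gaps), a
grass-clover ley (N-fixing forage) and a feed grain, livestock with
ruminant/monogastric diet structure, and trade tables (origin shares,
transport 50–300 kg CO₂e t⁻¹, LUC 2–15 t CO₂e ha⁻¹ yr⁻¹, COC 1–5 kg
CO₂e kg⁻¹). Coefficients are bounded uniform draws — tractable for
feasibility reasoning. Baseline supply and demand are set from the solved
conventional optimum (demand fraction 1.0 by default), which guarantees
caps are consistent and organic shortfalls are structural consequences of
the yield gap and ley requirement rather than accidents of the draw. Both
systems' LPs are solved at generation time; an infeasible draw raises a
diagnostic naming the violated resource rows.

What the generator does **not** emulate: real magnitudes or their
correlations (yields and prices are independent draws), spatial structure,
multi-year rotations as explicit sequences, price endogeneity, dietary
change. Passing tests therefore demonstrate the correctness of the
machinery — optimisation, accounting identities, uncertainty arithmetic —
on systems with the right shape, not the realism of any particular
national estimate.

Three archetypes with hand-computable optima back the solver tests:
`single_crop` (one crop, one class: plant everything), `two_crop_cap`
(higher-ME crop pinned at its 150% cap), `n_limited` (legume/cereal split
fixed by the N balance; cross-checked against exhaustive 0.01-ha grid
enumeration).

## Numerical choices and problem sizes

Feasibility tolerance 1e-9; binding-constraint detection at 1e-6 relative
slack; production identities asserted at 1e-6 relative; allocation
conservation at 1e-9. Test economies use 2 farm types × 3–5 crops × 0–2
livestock on 16 land classes (LPs of ~100–300 columns, solving in
milliseconds); Monte-Carlo checks use 10⁵ draws where a 2% tolerance on a
sample sd is asserted and 2,000 draws where only means and ordering
matter. Brute-force LP oracles use 0.01-ha grids in two dimensions and
0.05-ha in three.

## Known limitations

- One N pool per farm type; no explicit rotation sequencing or P/K cycles
  (assumed maintained by permitted minerals).
- Livestock mortality and feed-conversion detail are carried as activity
  coefficients, not simulated.
- Import archetypes reuse domestic emission profiles; region-specific LCAs
  would be config inputs.
- The gas-fraction split attributes LUC and sequestration wholly to CO₂,
  which is correct for the fluxes modelled but ignores N₂O from conversion
  transients.
- Significance testing assumes independent, approximately normal totals;
  Monte-Carlo totals from triangular inputs satisfy this well at the
  default n_sims.
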