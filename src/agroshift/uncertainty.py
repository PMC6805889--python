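"""Monte-Carlo uncertainty propagation and the z significance test.

Input uncertainties are expressed as symmetric triangular distributions whose
upper and lower bounds sit at a stated fraction of the mean (a 10% "uncertainty
estimate" means bounds at mean ± 10%).  The standard deviation of such a
triangular is mean * f / sqrt(6), which is smaller than mean * f — the
half-width fraction f is therefore NOT a coefficient of variation.  Both
conventions appear in LCA practice; here half-width fractions drive the
sampling and true CVs (sd/mean, in percent) drive the z test, and the two are
never interchanged.

Correlation structure: some error sources apply to a whole block of components
at once (e.g. a single land-area error applied to every area in one LP
solution, or one multiplier for all imported commodities en bloc).  Within a
block one shared triangular multiplier is drawn per simulation; across blocks
draws are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "UncertaintySpec",
    "ZTestInput",
    "ZTestResult",
    "sample_triangular",
    "sector_uncertainty",
    "combine_components",
    "z_test",
    "Z_THRESHOLD",
]

#: two-sided 5% significance threshold for the z statistic
Z_THRESHOLD = 1.96

#: sd of a symmetric triangular with half-width h is h / sqrt(6)
TRIANGULAR_SD_FACTOR = 1.0 / np.sqrt(6.0)


@dataclass(frozen=True)
class UncertaintySpec:
    """Half-width fractions (stored as percent) for each error source.

    Defaults: 10% per domestic crop commodity, 15% per domestic livestock
    commodity, 15% for all imported commodities as one block, 10% for import
    transport, 15% for the LP land-area solution as one block, 17% for LUC
    emission factors, 26% for carbon-opportunity-cost factors, 86% for the
    high sequestration rate and 24% for the lower rates.
    """

    cv_domestic_crop: float = 10.0
    cv_domestic_livestock: float = 15.0
    cv_imports_en_bloc: float = 15.0
    cv_transport: float = 10.0
    cv_land_area_solution: float = 15.0
    cv_luc: float = 17.0
    cv_coc: float = 26.0
    cv_seq_high: float = 86.0
    cv_seq_lower: float = 24.0
    n_sims: int = 10_000
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        for name in (
            "cv_domestic_crop", "cv_domestic_livestock", "cv_imports_en_bloc",
            "cv_transport", "cv_land_area_solution", "cv_luc", "cv_coc",
            "cv_seq_high", "cv_seq_lower",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    def seq_cv(self, seq_rate: float, high_rate: float = 0.18) -> float:
        """Half-width percent for a sequestration rate: the high rate carries
        the large (86%) uncertainty, lower rates 24%."""
        return self.cv_seq_high if np.isclose(seq_rate, high_rate) else self.cv_seq_lower


@dataclass(frozen=True)
class ZTestInput:
    """Means (same units) and their percent CVs (sd/mean * 100) for two systems."""

    m_a: float
    m_b: float
    cv_a: float
    cv_b: float

    def __post_init__(self) -> None:
        if self.m_a <= 0 or self.m_b <= 0:
            raise ValueError("means must be > 0")
        if self.cv_a < 0 or self.cv_b < 0:
            raise ValueError("CVs must be >= 0")


@dataclass(frozen=True)
class ZTestResult:
    z: float
    significant: bool


def sample_triangular(
    mean: float, half_width_fraction: float, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Draw from the symmetric triangular on [mean(1-f), mean(1+f)].

    f = 0 degenerates to a point mass at the mean.  Negative means are
    supported (bounds are swapped as needed), so sequestration credits can be
    perturbed with the same machinery.
    """
    if not np.isfinite(mean):
        raise ValueError("mean must be finite")
    if half_width_fraction < 0:
        raise ValueError("half-width fraction must be >= 0")
    if half_width_fraction == 0 or mean == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    lo = mean * (1.0 - half_width_fraction)
    hi = mean * (1.0 + half_width_fraction)
    lo, hi = min(lo, hi), max(lo, hi)
    draws = rng.triangular(lo, mean, hi, size=size)
    return draws if size is not None else float(draws)


def triangular_sd(mean: float, half_width_fraction: float) -> float:
    """Closed-form sd of the symmetric triangular: |mean| * f / sqrt(6)."""
    return abs(mean) * half_width_fraction * TRIANGULAR_SD_FACTOR


def sector_uncertainty(
    commodity_emissions: Sequence[tuple[float, float]],
    n_sims: int,
    seed: int | np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo (mean, sd) of a sector total from per-commodity means.

    Each commodity is (mean, half-width percent); per simulation every
    commodity is drawn independently from its triangular and the draws are
    summed.  Returns the sample mean and sd (ddof=1) of the simulated totals.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not commodity_emissions:
        raise ValueError("no commodities given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = np.zeros(n_sims)
    for mean, pct in commodity_emissions:
        totals += sample_triangular(mean, pct / 100.0, rng, size=n_sims)
    return float(totals.mean()), float(totals.std(ddof=1))


def combine_components(
    components: Sequence[tuple[float, float]],
    correlated_blocks: Sequence[Sequence[int]] | None,
    n_sims: int,
    seed: int | np.random.Generator,
) -> tuple[float, float]:
    """Combine component (mean, half-width percent) pairs into a total.

    ``correlated_blocks`` partitions component indices; within a block a
    single triangular multiplier (mode 1) is drawn per simulation and applied
    to every member — fully correlated errors, e.g. one land-area factor for
    all LP-derived areas.  Unlisted components form singleton blocks.  Blocks
    are mutually independent.  Returns (sample mean, sample sd) of the totals.
    """
    if not components:
        raise ValueError("empty component list")
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(components)
    blocks = [list(b) for b in (correlated_blocks or [])]
    seen = {i for b in blocks for i in b}
    if len(seen) != sum(len(b) for b in blocks):
        raise ValueError("correlated blocks overlap")
    if not seen <= set(range(n)):
        raise ValueError("block index out of range")
    blocks.extend([i] for i in range(n) if i not in seen)

    totals = np.zeros(n_sims)
    for block in blocks:
        # one shared relative error per block; members must share a half-width
        fracs = {components[i][1] for i in block}
        if len(fracs) != 1:
            raise ValueError("components in one correlated block must share a half-width")
        frac = fracs.pop() / 100.0
        multiplier = sample_triangular(1.0, frac, rng, size=n_sims)
        block_mean = sum(components[i][0] for i in block)
        totals += block_mean * multiplier
    return float(totals.mean()), float(totals.std(ddof=1))


def z_test(inp: ZTestInput, threshold: float = Z_THRESHOLD) -> ZTestResult:
    """Significance of a difference in means given their percent CVs.

        z = |m_A - m_B| / sqrt((CV_A*m_A/100)^2 + (CV_B*m_B/100)^2)

    The denominator is the sd of the difference of independent estimates
    (CV*m/100 converts each percent CV back to an sd); significance at the 5%
    level requires z >= 1.96.  Equal sds of zero with differing means is an
    infinitely significant difference and returns z = inf.
    """
    sd_a = inp.cv_a * inp.m_a / 100.0
    sd_b = inp.cv_b * inp.m_b / 100.0
    denom = np.hypot(sd_a, sd_b)
    diff = abs(inp.m_a - inp.m_b)
    if denom == 0:
        z = 0.0 if diff == 0 else float("inf")
    else:
        z = diff / denom
    return ZTestResult(z=float(z), significant=z >= threshold)


def cv_percent(mean: float, sd: float) -> float:
    """Percent CV = 100 * sd / mean (mean must be nonzero)."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / abs(mean)
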