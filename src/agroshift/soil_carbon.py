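"""Single-pool soil organic carbon model.

The model is the first-order balance

    dC/dt = I - k*C

where ``C`` is the soil C stock (Mg C ha^-1), ``I`` the annual C input from
vegetation and other sources (Mg C ha^-1 yr^-1) and ``k`` a first-order
decomposition rate constant (yr^-1).  Its steady state is ``I/k``: soils above
it lose carbon, soils below it sequester.  A land-use transition (e.g. from
continuous arable to rotational grass in an organic rotation) is summarised by
the mean of the initial sequestration rate ``I - k*C0`` and the zero rate at
the new steady state, applied as a flat annual rate over the transition.

Stocks and rates are in Mg C ha^-1 and Mg C ha^-1 yr^-1 throughout; CO2
equivalents use the 44/12 molar mass ratio with sequestration (a C gain)
reported as a negative emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SoilCarbonParams",
    "AreaWeights",
    "steady_state",
    "trajectory",
    "transition_rate",
    "area_weighted_rate",
    "time_to_steady_state",
    "c_to_co2",
    "fit_single_pool",
]

#: molar mass ratio CO2 / C
CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class SoilCarbonParams:
    """Parameters of the single-pool model for one land-use class.

    Attributes
    ----------
    input_rate : float
        Annual C input ``I`` (Mg C ha^-1 yr^-1).
    decay_constant : float
        Decomposition rate constant ``k`` (yr^-1), > 0.
    initial_stock : float
        Stock ``C0`` at t = 0 (Mg C ha^-1).
    """

    input_rate: float
    decay_constant: float
    initial_stock: float

    def __post_init__(self) -> None:
        if self.decay_constant <= 0:
            raise ValueError(f"decay constant must be > 0, got {self.decay_constant}")
        if self.initial_stock < 0:
            raise ValueError(f"stock must be >= 0, got {self.initial_stock}")

    @property
    def steady_state(self) -> float:
        return steady_state(self.input_rate, self.decay_constant)


@dataclass(frozen=True)
class AreaWeights:
    """Site counts used to area-weight a transition rate.

    ``n_arable`` sites can sequester on conversion to rotational grass;
    ``n_rotational_grass`` sites are taken to be at steady state already.
    """

    n_arable: int
    n_rotational_grass: int

    def __post_init__(self) -> None:
        if self.n_arable <= 0 or self.n_rotational_grass < 0:
            raise ValueError("site counts must be positive (rotational grass may be 0)")

    @property
    def arable_fraction(self) -> float:
        return self.n_arable / (self.n_arable + self.n_rotational_grass)


def steady_state(input_rate: float, decay_constant: float) -> float:
    """Steady-state stock I/k (Mg C ha^-1), where dC/dt = 0."""
    if decay_constant <= 0:
        raise ValueError(f"decay constant must be > 0, got {decay_constant}")
    return input_rate / decay_constant


def trajectory(params: SoilCarbonParams, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form stock C(t) = I/k + (C0 - I/k) exp(-k t).

    Monotone from C0 toward the steady state I/k; vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    c_star = params.steady_state
    out = c_star + (params.initial_stock - c_star) * np.exp(-params.decay_constant * t)
    return float(out) if out.ndim == 0 else out


def transition_rate(
    input_rate: float, decay_constant: float, initial_stock: float
) -> float:
    """Mean sequestration rate over a transition to a new steady state.

    The rate declines from ``I - k*C0`` initially to zero at steady state; the
    flat-rate summary is their mean, ``(I - k*C0) / 2`` (Mg C ha^-1 yr^-1).
    Positive values are sequestration, negative values are loss.
    """
    if decay_constant <= 0:
        raise ValueError(f"decay constant must be > 0, got {decay_constant}")
    return ((input_rate - decay_constant * initial_stock) + 0.0) / 2.0


def area_weighted_rate(rate: float, weights: AreaWeights) -> float:
    """Scale a per-hectare transition rate by the fraction of eligible sites.

    Only former-arable land sequesters; land already under rotational grass is
    at steady state, so the landscape-mean rate is
    ``rate * n_arable / (n_arable + n_rotational_grass)``.
    """
    return rate * weights.arable_fraction


def time_to_steady_state(
    c_star: float, c0: float, rate: float, *, round_to: int | None = None
) -> float:
    """Years to reach the new steady state at a flat annual rate.

    (C* - C0) / rate; ``round_to`` applies output rounding (e.g. 0 for whole
    years as conventionally reported) while full precision is the default.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if c_star < c0:
        raise ValueError("target stock below initial stock; rate sign convention violated")
    years = (c_star - c0) / rate
    return round(years, round_to) if round_to is not None else years


def c_to_co2(mass_c: float) -> float:
    """Convert Mg C to Mg CO2 (x 44/12).

    Magnitude conversion only; under the sequestration sign convention a
    positive C gain enters GHG budgets as a negative CO2 emission.
    """
    return mass_c * CO2_PER_C


def fit_single_pool(
    observations: Sequence[tuple[float, float]], *, mode: str = "rate"
) -> tuple[float, float]:
    """Least-squares fit of (I, k) to observations.

    Parameters
    ----------
    observations
        With ``mode="rate"``: pairs (C stock, dC/dt) — the fit is ordinary
        linear least squares on dC/dt = I - k*C.
        With ``mode="series"``: pairs (t, C) from one trajectory — the fit is
        nonlinear least squares on the closed-form solution with C0 taken from
        the earliest observation.

    Returns
    -------
    (I, k) : tuple of float

    Raises
    ------
    ValueError
        For fewer than two observations or a degenerate design (all C equal
        in rate mode; fewer than three distinct times in series mode).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise ValueError("need at least two (x, y) observations")

    if mode == "rate":
        c, dcdt = obs[:, 0], obs[:, 1]
        if np.ptp(c) == 0:
            raise ValueError("degenerate design: all C stocks equal")
        # dC/dt = I - k*C  ->  regress dC/dt on C
        design = np.column_stack([np.ones_like(c), -c])
        (intercept, slope), *_ = np.linalg.lstsq(design, dcdt, rcond=None)
        return float(intercept), float(slope)

    if mode == "series":
        order = np.argsort(obs[:, 0])
        t, c = obs[order, 0], obs[order, 1]
        if len(np.unique(t)) < 3:
            raise ValueError("series fit needs at least three distinct times")
        c0 = c[0]

        def model(tt: np.ndarray, i: float, k: float) -> np.ndarray:
            return i / k + (c0 - i / k) * np.exp(-k * tt)

        k0 = 0.05
        i0 = max(c.mean() * k0, 1e-6)
        popt, _ = optimize.curve_fit(
            model, t - t[0], c, p0=(i0, k0), bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000
        )
        return float(popt[0]), float(popt[1])

    raise ValueError(f"unknown mode {mode!r}; expected 'rate' or 'series'")
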