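"""Value-of-statistical-life benefit transfer and monetization.

The 1990 US VSL is drawn from a Weibull distribution, grown to the target
year with an income elasticity on real GDP per capita and the price
deflator, then transferred to the target country with the PPP income ratio
raised to the cross-country elasticity:

    V = [V_1990 * (G_y / G_1990)**eps1 * D_y / D_1990] * R_y**eps2

Mortality and VSL draws are paired index-to-index, so each Monte Carlo
realization carries one coherent (deaths, VSL) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .synthetic_world.types import EconSeries

__all__ = ["VSLEstimate", "MonetizedCost", "vsl_transfer", "monetize"]


@dataclass(frozen=True)
class VSLEstimate:
    """Per-year transferred VSL draws (million USD) with summary stats."""

    year: int
    draws: np.ndarray = field(repr=False)
    vsl_mean: float = 0.0
    vsl_ci: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", d)
        if np.any(d <= 0):
            raise ValueError("VSL draws must be positive")
        if not (self.vsl_ci[0] <= self.vsl_mean <= self.vsl_ci[1]):
            raise ValueError("CI must bracket the mean")


@dataclass(frozen=True)
class MonetizedCost:
    """Monetized mortality cost, USD per year, with percentile CI."""

    cost_mean: float
    cost_ci: tuple[float, float]
    draws: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cost_mean < 0 or self.cost_ci[0] < 0:
            raise ValueError("cost must be non-negative")


def vsl_transfer(
    econ: EconSeries, year: int, n_draws: int = 1000, seed: int = 0
) -> VSLEstimate:
    """Transfer the 1990 US VSL to the target country for one year."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    row = econ.row(year)  # raises KeyError naming the year if absent
    base = econ.row(econ.base_year)
    rng = substream(seed, "valuation.vsl")
    v_us_1990 = econ.vsl_us_1990_scale * rng.weibull(econ.vsl_us_1990_shape, n_draws)
    # degenerate Weibull draws of exactly zero are measure-zero but guard anyway
    v_us_1990 = np.maximum(v_us_1990, 1e-12)
    growth = (
        (row["gdp_per_capita_us"] / base["gdp_per_capita_us"]) ** econ.epsilon1
        * row["gdp_deflator"]
        / base["gdp_deflator"]
    )
    income_factor = row["ppp_ratio"] ** econ.epsilon2
    draws = v_us_1990 * growth * income_factor
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return VSLEstimate(
        year=int(year),
        draws=draws,
        vsl_mean=float(draws.mean()),
        vsl_ci=(float(lo), float(hi)),
    )


def monetize(death_draws: np.ndarray, vsl: VSLEstimate) -> MonetizedCost:
    """Per-draw product of deaths and VSL, summarized over draws.

    ``vsl`` draws are in million USD; the returned cost is in USD.
    """
    deaths = np.asarray(death_draws, dtype=float)
    if deaths.shape != vsl.draws.shape:
        raise ValueError(
            f"draw counts differ: {deaths.shape[0]} deaths vs "
            f"{vsl.draws.shape[0]} VSL draws"
        )
    draws = deaths * vsl.draws * 1.0e6
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return MonetizedCost(
        cost_mean=float(draws.mean()),
        cost_ci=(float(lo), float(hi)),
        draws=draws,
    )
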