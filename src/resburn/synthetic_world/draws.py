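"""Stochastic input tables: exposure-response draws, demography, economics.

Magnitudes are plausible stand-ins, not real-world estimates. Each generator is
deterministic for a fixed seed via a named sub-stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import substream
from .types import CAUSES, DemographyTable, EconSeries, IERParameterDraws

__all__ = ["draw_ier_params", "make_demography", "make_econ_series"]

# central (alpha, beta, delta) per cause; draws scatter around these
_IER_CENTERS = {
    "COPD": (0.9, 0.03, 0.7),
    "IHD": (1.4, 0.06, 0.55),
    "LRI": (1.1, 0.04, 0.65),
    "lung_cancer": (0.8, 0.02, 0.75),
    "cerebrovascular": (1.2, 0.05, 0.6),
}

_AGE_GROUPS = ("under_25", "25_49", "50_69", "70_plus")
_AGE_SHARES = (0.44, 0.33, 0.17, 0.06)

# all-age baseline mortality per cause (deaths per person per year)
_BMR_ALL_AGE = {
    "COPD": 6.0e-4,
    "IHD": 1.5e-3,
    "LRI": 5.0e-4,
    "lung_cancer": 6.0e-5,
    "cerebrovascular": 7.0e-4,
}

# how steeply each cause's mortality rises with age (relative multipliers)
_BMR_AGE_PROFILE = {
    "COPD": (0.02, 0.3, 2.2, 8.0),
    "IHD": (0.02, 0.5, 2.5, 7.0),
    "LRI": (0.6, 0.4, 1.5, 6.0),
    "lung_cancer": (0.01, 0.4, 2.8, 6.5),
    "cerebrovascular": (0.02, 0.4, 2.4, 7.5),
}

# excess-relative-risk multipliers by age; only the two cardiovascular/
# cerebrovascular causes vary with age, the rest use an all-age risk
_RR_AGE_SCALE = {
    "COPD": (1.0, 1.0, 1.0, 1.0),
    "IHD": (1.0, 1.35, 1.0, 0.65),
    "LRI": (1.0, 1.0, 1.0, 1.0),
    "lung_cancer": (1.0, 1.0, 1.0, 1.0),
    "cerebrovascular": (1.0, 1.3, 1.0, 0.7),
}


def draw_ier_params(n_draws: int = 1000, seed: int = 0) -> IERParameterDraws:
    """Draw per-cause (alpha, beta, delta, chi0) quadruples.

    chi0 is uniform on the theoretical minimum-risk range [2.4, 5.9];
    the shape parameters scatter lognormally around per-cause centers.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = substream(seed, "draws.ier")
    lo, hi = IERParameterDraws.CHI0_RANGE
    frames = []
    for cause in CAUSES:
        a0, b0, d0 = _IER_CENTERS[cause]
        frames.append(
            pd.DataFrame(
                {
                    "cause": cause,
                    "draw": np.arange(n_draws),
                    "alpha": a0 * rng.lognormal(0.0, 0.15, n_draws),
                    "beta": b0 * rng.lognormal(0.0, 0.2, n_draws),
                    "delta": d0 * rng.lognormal(0.0, 0.1, n_draws),
                    "chi0": rng.uniform(lo, hi, n_draws),
                }
            )
        )
    params = pd.concat(frames, ignore_index=True)
    return IERParameterDraws(params=params, n_draws=n_draws)


def make_demography(seed: int = 0) -> DemographyTable:
    """Age shares, cause- and age-specific baseline mortality, RR age scaling."""
    rng = substream(seed, "draws.demography")
    shares = np.asarray(_AGE_SHARES, dtype=float)
    shares = shares / shares.sum()
    bmr_rows = {}
    for cause in CAUSES:
        profile = np.asarray(_BMR_AGE_PROFILE[cause], dtype=float)
        # jitter the all-age level, then spread it over ages so that the
        # share-weighted mean equals the all-age rate
        level = _BMR_ALL_AGE[cause] * rng.lognormal(0.0, 0.1)
        profile = profile / float(profile @ shares)
        bmr_rows[cause] = level * profile
    bmr = pd.DataFrame.from_dict(bmr_rows, orient="index", columns=list(_AGE_GROUPS))
    rr_scale = pd.DataFrame.from_dict(
        {c: np.asarray(_RR_AGE_SCALE[c], dtype=float) for c in CAUSES},
        orient="index",
        columns=list(_AGE_GROUPS),
    )
    return DemographyTable(
        age_groups=_AGE_GROUPS, age_share=shares, bmr=bmr, rr_age_scale=rr_scale
    )


def make_econ_series(years=range(1990, 2020), seed: int = 0) -> EconSeries:
    """Annual US GDP per capita, deflator, and PPP income ratio series."""
    years = np.array(sorted(years), dtype=int)
    if len(years) == 0:
        raise ValueError("need at least one year")
    rng = substream(seed, "draws.econ")
    n = len(years)
    # smooth growth with small seeded noise; all series strictly positive
    gdp_growth = 0.022 + rng.normal(0.0, 0.004, n)
    deflator_growth = 0.021 + rng.normal(0.0, 0.003, n)
    ratio_growth = 0.035 + rng.normal(0.0, 0.005, n)
    base_idx = int(np.argmin(np.abs(years - 1990)))
    # anchor each series so the base year hits its intended level exactly
    gdp = np.exp(np.cumsum(gdp_growth))
    gdp *= 23000.0 / gdp[base_idx]
    deflator = np.exp(np.cumsum(deflator_growth))
    deflator *= 100.0 / deflator[base_idx]
    ratio = np.exp(np.cumsum(ratio_growth))
    ratio = np.minimum(ratio * (0.055 / ratio[base_idx]), 0.99)
    table = pd.DataFrame(
        {
            "gdp_per_capita_us": gdp,
            "gdp_deflator": deflator,
            "ppp_ratio": ratio,
        },
        index=pd.Index(years, name="year"),
    )
    base_year = int(years[base_idx])
    return EconSeries(table=table, base_year=base_year)
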