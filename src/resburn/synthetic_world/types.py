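"""Core domain containers for the synthetic world.

Array conventions: 2-D cell fields are ``(n_lat, n_lon)``; time-resolved
fields are ``(n_steps, n_lat, n_lon)`` with time as the leading axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CAUSES",
    "GridSpec",
    "PopulationGrid",
    "RegionMap",
    "CropTable",
    "TransportConfig",
    "EmissionInventory",
    "DemographyTable",
    "IERParameterDraws",
    "EconSeries",
    "ConcentrationField",
]

#: The five causes of death carried through the mortality chain.
CAUSES = ("COPD", "IHD", "LRI", "lung_cancer", "cerebrovascular")


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with an hourly (or coarser) clock.

    Parameters
    ----------
    n_lon, n_lat
        Number of cells in each direction; both must be >= 2.
    cell_area
        Area of one cell in km².
    n_days
        Number of simulated days.
    steps_per_day
        Time steps per day; must divide 24 evenly (24 means hourly).
    local_time_offset
        Hours offset from simulation clock to local time, per lon column
        (a scalar applies everywhere). Zero by default: a single time zone.
    """

    n_lon: int
    n_lat: int
    cell_area: float = 1000.0
    n_days: int = 60
    steps_per_day: int = 24
    local_time_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.n_lat}x{self.n_lon}"
            )
        if self.steps_per_day <= 0 or 24 % self.steps_per_day != 0:
            raise ValueError(
                f"steps_per_day must divide 24, got {self.steps_per_day}"
            )
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def n_steps(self) -> int:
        return self.n_days * self.steps_per_day

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def hour_of_step(self, t: int) -> int:
        """Local-time hour bin (0..23) of time step ``t``."""
        return (t % self.steps_per_day) * (24 // self.steps_per_day)

    def day_of_step(self, t: int) -> int:
        return t // self.steps_per_day


@dataclass(frozen=True)
class PopulationGrid:
    """People per cell; density is ``rho / cell_area``."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if np.any(rho < 0):
            raise ValueError("population must be non-negative everywhere")
        if rho.sum() <= 0:
            raise ValueError("total population must be positive")

    @property
    def total(self) -> float:
        return float(self.rho.sum())

    def density(self, cell_area: float) -> np.ndarray:
        return self.rho / cell_area


@dataclass(frozen=True)
class RegionMap:
    """Nested country/state/district integer labels per grid cell."""

    country_id: np.ndarray
    state_id: np.ndarray
    district_id: np.ndarray
    names: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level in ("country_id", "state_id", "district_id"):
            arr = np.asarray(getattr(self, level), dtype=int)
            object.__setattr__(self, level, arr)
        if not (self.country_id.shape == self.state_id.shape == self.district_id.shape):
            raise ValueError("region label arrays must share one shape")
        # nesting: each district maps to exactly one state, each state to one country
        for child, parent, what in (
            (self.district_id, self.state_id, "district->state"),
            (self.state_id, self.country_id, "state->country"),
        ):
            pairs = {(int(c), int(p)) for c, p in zip(child.ravel(), parent.ravel())}
            children = [c for c, _ in pairs]
            if len(children) != len(set(children)):
                raise ValueError(f"nesting violated at level {what}")

    @property
    def districts(self) -> np.ndarray:
        return np.unique(self.district_id)

    @property
    def states(self) -> np.ndarray:
        return np.unique(self.state_id)

    @property
    def countries(self) -> np.ndarray:
        return np.unique(self.country_id)

    def labels(self, level: str) -> np.ndarray:
        """Per-cell label array for ``level`` in {district, state, country}."""
        try:
            return getattr(self, f"{level}_id")
        except AttributeError:
            raise ValueError(f"unknown region level: {level!r}") from None

    def cells_of(self, level: str, region_id: int) -> np.ndarray:
        """Boolean cell mask of one region."""
        return self.labels(level) == region_id

    def name_of(self, level: str, region_id: int) -> str:
        return self.names.get((level, int(region_id)), f"{level}_{int(region_id)}")

    def state_of_district(self, district_id: int) -> int:
        return int(self.state_id[self.district_id == district_id][0])

    def country_of_state(self, state_id: int) -> int:
        return int(self.country_id[self.state_id == state_id][0])


@dataclass(frozen=True)
class CropTable:
    """Per-district crop production and burning characteristics.

    Columns of ``table`` (indexed by district id):

    - ``production``: crop output, MT per year
    - ``residue_ratio``: residue MT per crop MT
    - ``burned_fraction``: fraction of residue burned, in [0, 1]
    - ``emission_factor``: kg PM2.5 (BC+OC) per MT residue burned
    """

    table: pd.DataFrame

    REQUIRED = ("production", "residue_ratio", "burned_fraction", "emission_factor")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"CropTable missing columns: {missing}")
        tab = self.table
        if (tab[list(self.REQUIRED)] < 0).any().any():
            raise ValueError("CropTable fields must be non-negative")
        if (tab["burned_fraction"] > 1).any():
            raise ValueError("burned_fraction must be <= 1")

    @property
    def districts(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def annual_emission_kg(self) -> pd.Series:
        """Annual burning emissions per district (kg)."""
        t = self.table
        out = (
            t["production"]
            * t["residue_ratio"]
            * t["burned_fraction"]
            * t["emission_factor"]
        )
        out.name = "annual_emission_kg"
        return out


@dataclass(frozen=True)
class TransportConfig:
    """Parameters of the linear toy transport operator.

    One step applies, in order: upwind advection (outflow boundaries),
    5-point diffusion, linear deposition decay, then injection of fresh
    emissions diluted by the diurnal mixing-depth cycle.
    """

    wind: tuple[float, float] = (0.45, 0.15)
    diffusion: float = 0.06
    deposition_rate: float = 0.05
    mixing_depth_cycle: np.ndarray = field(
        default_factory=lambda: _default_mixing_cycle()
    )
    emission_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing_depth_cycle, dtype=float)
        object.__setattr__(self, "mixing_depth_cycle", mix)
        u, v = self.wind
        if not (abs(u) <= 1 and abs(v) <= 1):
            raise ValueError("|wind components| must be <= 1 cell per step")
        if not (0 <= self.diffusion <= 0.25):
            # 4k <= 1 keeps all one-step operator entries non-negative
            raise ValueError("diffusion weight must lie in [0, 0.25]")
        if not (0 < self.deposition_rate < 1):
            raise ValueError("deposition_rate must lie in (0, 1)")
        if mix.shape != (24,) or np.any(mix <= 0):
            raise ValueError("mixing_depth_cycle needs 24 positive values")
        if self.emission_scale <= 0:
            raise ValueError("emission_scale must be positive")


def _default_mixing_cycle() -> np.ndarray:
    """Diurnal dilution multipliers, maximal in the 13:00-14:00 bin."""
    hours = np.arange(24) + 0.5
    return 1.0 + 5.0 * np.exp(-0.5 * ((hours - 13.2) / 3.0) ** 2)


@dataclass(frozen=True)
class EmissionInventory:
    """Gridded burning emissions, kg per cell per period.

    ``E`` has shape ``(n_days, n_lat, n_lon)`` at daily resolution or
    ``(n_days * steps_per_day, n_lat, n_lon)`` at hourly resolution.
    """

    E: np.ndarray
    resolution: str  # "daily" | "hourly"
    season_of_day: tuple[str, ...]
    species: str = "PM2.5_BCOC"

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "season_of_day", tuple(self.season_of_day))
        if self.resolution not in ("daily", "hourly"):
            raise ValueError(f"resolution must be daily or hourly, got {self.resolution!r}")
        if np.any(E < 0):
            raise ValueError("emissions must be non-negative")
        if self.resolution == "daily" and E.shape[0] != len(self.season_of_day):
            raise ValueError("daily inventory needs one season label per day")
        if self.resolution == "hourly" and E.shape[0] % len(self.season_of_day) != 0:
            raise ValueError("hourly inventory length must be a multiple of n_days")

    @property
    def n_days(self) -> int:
        return len(self.season_of_day)

    @property
    def steps_per_day(self) -> int:
        return self.E.shape[0] // self.n_days

    def total(self) -> float:
        return float(self.E.sum())

    def daily_totals(self) -> np.ndarray:
        """Per-day grid totals (kg), regardless of resolution."""
        if self.resolution == "daily":
            return self.E.sum(axis=(1, 2))
        per_step = self.E.sum(axis=(1, 2))
        return per_step.reshape(self.n_days, self.steps_per_day).sum(axis=1)

    def days_in_season(self, season: str) -> np.ndarray:
        return np.array([s == season for s in self.season_of_day])


@dataclass(frozen=True)
class DemographyTable:
    """Age structure, baseline mortality rates, and age risk weighting.

    ``bmr`` and ``rr_age_scale`` are DataFrames indexed by cause with one
    column per age group. ``rr_age_scale`` multiplies the excess relative
    risk (RR - 1) per age group; it differs from 1 only for the causes whose
    risk varies with age (IHD, cerebrovascular).
    """

    age_groups: tuple[str, ...]
    age_share: np.ndarray
    bmr: pd.DataFrame
    rr_age_scale: pd.DataFrame

    def __post_init__(self) -> None:
        share = np.asarray(self.age_share, dtype=float)
        object.__setattr__(self, "age_share", share)
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        if abs(share.sum() - 1.0) > 1e-9:
            raise ValueError("age shares must sum to 1")
        if np.any(share < 0):
            raise ValueError("age shares must be non-negative")
        for df, what in ((self.bmr, "bmr"), (self.rr_age_scale, "rr_age_scale")):
            if set(df.index) != set(CAUSES):
                raise ValueError(f"{what} must cover exactly the causes {CAUSES}")
            if list(df.columns) != list(self.age_groups):
                raise ValueError(f"{what} columns must match age_groups")
            if (df < 0).any().any():
                raise ValueError(f"{what} must be non-negative")


@dataclass(frozen=True)
class IERParameterDraws:
    """Per-cause Monte Carlo draws of the exposure-response parameters.

    ``params`` is a long-format DataFrame with columns
    (cause, draw, alpha, beta, delta, chi0).
    """

    params: pd.DataFrame
    n_draws: int

    CHI0_RANGE = (2.4, 5.9)

    def __post_init__(self) -> None:
        need = {"cause", "draw", "alpha", "beta", "delta", "chi0"}
        if not need.issubset(self.params.columns):
            raise ValueError(f"params must have columns {sorted(need)}")
        if set(self.params["cause"]) != set(CAUSES):
            raise ValueError("draws must cover exactly the five causes")
        counts = self.params.groupby("cause").size()
        if not (counts == self.n_draws).all():
            raise ValueError("each cause needs exactly n_draws rows")
        lo, hi = self.CHI0_RANGE
        chi0 = self.params["chi0"]
        if ((chi0 < lo) | (chi0 > hi)).any():
            raise ValueError(f"chi0 must lie within [{lo}, {hi}]")
        for col in ("alpha", "beta", "delta"):
            if (self.params[col] <= 0).any():
                raise ValueError(f"{col} must be positive")

    def arrays(self, cause: str) -> dict[str, np.ndarray]:
        """Parameter arrays of one cause, ordered by draw index."""
        sub = self.params[self.params["cause"] == cause].sort_values("draw")
        if sub.empty:
            raise KeyError(f"unknown cause: {cause!r}")
        return {c: sub[c].to_numpy() for c in ("alpha", "beta", "delta", "chi0")}


@dataclass(frozen=True)
class EconSeries:
    """Annual economic series plus the valuation scalars.

    ``table`` is indexed by year with columns ``gdp_per_capita_us`` (USD),
    ``gdp_deflator`` (index), ``ppp_ratio`` (target/US GDP-per-capita PPP
    ratio in (0, 1]). The 1990 US base value follows a Weibull distribution
    with the given shape/scale (scale in million USD).
    """

    table: pd.DataFrame
    vsl_us_1990_shape: float = 1.51
    vsl_us_1990_scale: float = 5.32
    epsilon1: float = 0.7
    epsilon2: float = 1.5
    base_year: int = 1990

    def __post_init__(self) -> None:
        need = {"gdp_per_capita_us", "gdp_deflator", "ppp_ratio"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"EconSeries table must have columns {sorted(need)}")
        if (self.table[sorted(need)] <= 0).any().any():
            raise ValueError("all economic series must be strictly positive")
        if (self.table["ppp_ratio"] > 1).any():
            raise ValueError("ppp_ratio must be <= 1")
        if self.base_year not in self.table.index:
            raise ValueError(f"base year {self.base_year} missing from series")
        if self.vsl_us_1990_shape <= 0 or self.vsl_us_1990_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def row(self, year: int) -> pd.Series:
        if year not in self.table.index:
            raise KeyError(f"year {year} not present in the economic series")
        return self.table.loc[year]


@dataclass(frozen=True)
class ConcentrationField:
    """Surface PM2.5 per cell per time step, µg m⁻³."""

    chi: np.ndarray

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        object.__setattr__(self, "chi", chi)
        if chi.ndim != 3:
            raise ValueError("chi must be (n_steps, n_lat, n_lon)")

    @property
    def n_steps(self) -> int:
        return self.chi.shape[0]
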