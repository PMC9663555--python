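"""Assemble a complete synthetic world from one config and one seed.

The world is deliberately structured so the pipeline has something to find:
an upwind (western) agricultural belt, a downwind urban cluster in the east
of the home country, and a small neighboring country on the eastern edge
that receives outflow. All magnitudes are order-of-magnitude plausible but
arbitrary stand-ins for real-world data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._rng import substream
from .draws import draw_ier_params, make_demography, make_econ_series
from .types import (
    CropTable,
    DemographyTable,
    EconSeries,
    GridSpec,
    IERParameterDraws,
    PopulationGrid,
    RegionMap,
    TransportConfig,
)

__all__ = ["WorldConfig", "World", "make_world", "default_seasons"]

SEASONS = ("pre_monsoon", "off_season", "post_monsoon")


@dataclass(frozen=True)
class WorldConfig:
    """Scenario parameters for :func:`make_world`."""

    n_lon: int = 6
    n_lat: int = 6
    cell_area: float = 1000.0  # km² per cell
    n_days: int = 60
    steps_per_day: int = 24
    n_countries: int = 2
    n_districts_home: int = 9  # districts in the home country
    districts_per_state: int = 3
    urban_fraction: float = 0.1  # fraction of home-country cells made urban
    rural_density: float = 80.0  # people per km², order of magnitude
    urban_density: float = 2500.0  # people per km², above the 1000 threshold
    background_chi: float = 60.0  # annual-mean non-fire PM2.5, µg m⁻³
    wind: tuple[float, float] = (0.45, 0.15)
    diffusion: float = 0.06
    deposition_rate: float = 0.05
    emission_scale: float = 1.5e5
    in_season_fraction: float = 0.97
    n_draws: int = 1000
    econ_years: tuple[int, int] = (1990, 2019)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_districts_home < 1:
            raise ValueError("need at least one district")
        if not (0 <= self.urban_fraction <= 1):
            raise ValueError("urban_fraction must lie in [0, 1]")
        if self.n_days < 3:
            raise ValueError("need enough days for two burning seasons")


@dataclass(frozen=True)
class World:
    """Everything the downstream pipeline consumes."""

    grid: GridSpec
    pop: PopulationGrid
    regions: RegionMap
    crops: CropTable
    transport: TransportConfig
    demography: DemographyTable
    ier_draws: IERParameterDraws
    econ: EconSeries
    season_of_day: tuple[str, ...]
    background_chi: float
    home_country: int = 0
    config: WorldConfig = field(default_factory=WorldConfig)

    def astuple(self):
        return (
            self.grid,
            self.pop,
            self.regions,
            self.crops,
            self.transport,
            self.demography,
            self.ier_draws,
            self.econ,
        )


def default_seasons(n_days: int) -> tuple[str, ...]:
    """Day -> season labels: first third pre-monsoon, last third post-monsoon."""
    third = n_days // 3
    labels = ["off_season"] * n_days
    for d in range(third):
        labels[d] = "pre_monsoon"
    for d in range(n_days - third, n_days):
        labels[d] = "post_monsoon"
    return tuple(labels)


def _make_regions(cfg: WorldConfig) -> RegionMap:
    """Tile the grid into nested regions; the last lon column is the neighbor."""
    n_lat, n_lon = cfg.n_lat, cfg.n_lon
    country = np.zeros((n_lat, n_lon), dtype=int)
    neighbor_cols = 1 if cfg.n_countries > 1 else 0
    if neighbor_cols:
        country[:, -neighbor_cols:] = 1

    district = np.full((n_lat, n_lon), -1, dtype=int)
    home_cols = n_lon - neighbor_cols
    # tile the home country into row x col blocks, close to n_districts_home
    n_row_blocks = max(1, int(round(np.sqrt(cfg.n_districts_home))))
    n_col_blocks = max(1, int(np.ceil(cfg.n_districts_home / n_row_blocks)))
    row_edges = np.linspace(0, n_lat, n_row_blocks + 1).astype(int)
    col_edges = np.linspace(0, home_cols, n_col_blocks + 1).astype(int)
    did = 0
    for rb in range(n_row_blocks):
        for cb in range(n_col_blocks):
            rows = slice(row_edges[rb], row_edges[rb + 1])
            cols = slice(col_edges[cb], col_edges[cb + 1])
            district[rows, cols] = did
            did += 1
    n_home_districts = did
    if neighbor_cols:
        district[:, -neighbor_cols:] = n_home_districts  # one neighbor district
    state = district // cfg.districts_per_state
    if neighbor_cols:
        state[:, -neighbor_cols:] = n_home_districts // cfg.districts_per_state + 1
    # countries from states
    names: dict[tuple[str, int], str] = {("country", 0): "Homeland"}
    if neighbor_cols:
        names[("country", 1)] = "Neighborland"
    for d in np.unique(district):
        names[("district", int(d))] = f"D{int(d):02d}"
    for s in np.unique(state):
        names[("state", int(s))] = f"S{int(s):02d}"
    return RegionMap(country_id=country, state_id=state, district_id=district, names=names)


def _make_population(cfg: WorldConfig, regions: RegionMap, rng: np.random.Generator) -> PopulationGrid:
    n_lat, n_lon = cfg.n_lat, cfg.n_lon
    # rural base: lognormal spread around rural_density, capped below the
    # 400 /km² urban threshold so only designated cells are "urban"
    density = cfg.rural_density * rng.lognormal(0.0, 0.4, size=(n_lat, n_lon))
    density = np.minimum(density, 390.0)
    home = regions.country_id == regions.country_id.min()
    home_cells = np.argwhere(home)
    n_urban = int(round(cfg.urban_fraction * home_cells.shape[0]))
    if cfg.urban_fraction > 0:
        n_urban = max(1, n_urban)
    if n_urban:
        # downwind cluster: prefer eastern home-country cells, middle latitudes
        order = np.lexsort(
            (np.abs(home_cells[:, 0] - n_lat / 2), -home_cells[:, 1])
        )
        chosen = home_cells[order[:n_urban]]
        dens_urban = cfg.urban_density * rng.lognormal(0.0, 0.25, size=n_urban)
        dens_urban = np.maximum(dens_urban, 1100.0)
        density[chosen[:, 0], chosen[:, 1]] = dens_urban
    return PopulationGrid(rho=density * cfg.cell_area)


def _make_crops(cfg: WorldConfig, regions: RegionMap, rng: np.random.Generator) -> CropTable:
    districts = regions.districts
    home = regions.country_id.min()
    rows = []
    # district centroid lon column, to boost upwind (western) production
    for d in districts:
        cells = regions.cells_of("district", int(d))
        is_home = regions.country_id[cells][0] == home
        col = np.argwhere(cells)[:, 1].mean()
        west_boost = 1.0 + 3.0 * max(0.0, 1.0 - col / max(1, cfg.n_lon - 1))
        if is_home:
            production = 8.0 * west_boost * rng.lognormal(0.0, 0.3)
            residue_ratio = rng.uniform(1.2, 1.8)
            burned_fraction = rng.uniform(0.15, 0.5)
            emission_factor = rng.uniform(3.0, 7.0)
        else:  # neighbor country does not burn residue in this world
            production = rng.lognormal(0.0, 0.3)
            residue_ratio = rng.uniform(1.2, 1.8)
            burned_fraction = 0.0
            emission_factor = rng.uniform(3.0, 7.0)
        rows.append(
            dict(
                district=int(d),
                production=production,
                residue_ratio=residue_ratio,
                burned_fraction=burned_fraction,
                emission_factor=emission_factor,
            )
        )
    table = pd.DataFrame(rows).set_index("district")
    return CropTable(table=table)


def make_world(config: WorldConfig | None = None, seed: int | None = None) -> World:
    """Build the full synthetic input stack, deterministically for a seed."""
    cfg = config or WorldConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    grid = GridSpec(
        n_lon=cfg.n_lon,
        n_lat=cfg.n_lat,
        cell_area=cfg.cell_area,
        n_days=cfg.n_days,
        steps_per_day=cfg.steps_per_day,
    )
    regions = _make_regions(cfg)
    pop = _make_population(cfg, regions, substream(cfg.seed, "world.population"))
    crops = _make_crops(cfg, regions, substream(cfg.seed, "world.crops"))
    transport = TransportConfig(
        wind=cfg.wind,
        diffusion=cfg.diffusion,
        deposition_rate=cfg.deposition_rate,
        emission_scale=cfg.emission_scale,
        seed=cfg.seed,
    )
    demography = make_demography(seed=cfg.seed)
    ier = draw_ier_params(n_draws=cfg.n_draws, seed=cfg.seed)
    econ = make_econ_series(
        years=range(cfg.econ_years[0], cfg.econ_years[1] + 1), seed=cfg.seed
    )
    return World(
        grid=grid,
        pop=pop,
        regions=regions,
        crops=crops,
        transport=transport,
        demography=demography,
        ier_draws=ier,
        econ=econ,
        season_of_day=default_seasons(cfg.n_days),
        background_chi=cfg.background_chi,
        config=cfg,
    )
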