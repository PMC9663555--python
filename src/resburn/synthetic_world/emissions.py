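"""Daily burning-emission inventories derived from the crop table.

District annual totals are fixed exactly by
``production x residue_ratio x burned_fraction x emission_factor``; the
spatial spread across a district's cells and the temporal spread across
burning-season days are seeded random weights that sum to one, so the
construction is linear in each district's production.
"""

from __future__ import annotations

import numpy as np

from .._rng import substream
from .types import CropTable, EmissionInventory, GridSpec, RegionMap
from .world import default_seasons

__all__ = ["make_emissions", "BURNING_SEASONS"]

BURNING_SEASONS = ("pre_monsoon", "post_monsoon")


def make_emissions(
    crops: CropTable,
    regions: RegionMap,
    grid: GridSpec,
    seed: int = 0,
    season_of_day: tuple[str, ...] | None = None,
    in_season_fraction: float = 0.97,
) -> EmissionInventory:
    """Daily gridded emissions whose district totals match the crop table.

    At least ``in_season_fraction`` of each district's annual total falls
    inside the two burning seasons (at least 90% by contract).
    """
    if season_of_day is None:
        season_of_day = default_seasons(grid.n_days)
    if len(season_of_day) != grid.n_days:
        raise ValueError("season_of_day must have one label per day")
    if not (0.9 <= in_season_fraction <= 1.0):
        raise ValueError("in_season_fraction must lie in [0.9, 1.0]")

    present = set(int(d) for d in regions.districts)
    missing = [int(d) for d in crops.districts if int(d) not in present]
    if missing:
        raise KeyError(
            f"districts {missing} in the crop table are absent from the region map"
        )

    seasons = np.asarray(season_of_day)
    in_season = np.isin(seasons, BURNING_SEASONS)
    if not in_season.any():
        raise ValueError("no burning-season days in the calendar")

    rng = substream(seed, "emissions")
    totals = crops.annual_emission_kg()
    E = np.zeros((grid.n_days, grid.n_lat, grid.n_lon))
    for d in crops.districts:
        total = float(totals.loc[d])
        if total == 0.0:
            continue
        cells = regions.cells_of("district", int(d))
        idx = np.argwhere(cells)
        spatial = rng.dirichlet(np.full(len(idx), 2.0))
        # temporal weights: in-season days carry in_season_fraction of mass
        w = np.zeros(grid.n_days)
        w_in = rng.dirichlet(np.full(int(in_season.sum()), 1.5))
        w[in_season] = in_season_fraction * w_in
        n_off = int((~in_season).sum())
        if n_off and in_season_fraction < 1.0:
            w[~in_season] = (1.0 - in_season_fraction) * rng.dirichlet(
                np.full(n_off, 1.5)
            )
        else:
            w[in_season] = w_in  # no off-season days: all mass in season
        daily = total * w
        for (j, i), s in zip(idx, spatial):
            E[:, j, i] += daily * s
    return EmissionInventory(E=E, resolution="daily", season_of_day=tuple(season_of_day))
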