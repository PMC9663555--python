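"""Counterfactual experiments: timing shifts, district categories, rankings."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .attribution import ExposureContribution, attribute
from .diurnal import DiurnalKernel, apply_kernel, shift_kernel
from .synthetic_world.transport import SensitivityField
from .synthetic_world.types import EmissionInventory, RegionMap

__all__ = [
    "DEFAULT_SHIFTS",
    "timing_shift_experiment",
    "categorize_districts",
    "rank_contributions",
]

#: Shifts evaluated by default: one to six hours earlier, one hour later.
DEFAULT_SHIFTS = (-6, -5, -4, -3, -2, -1, 1)


def _scoped_total(
    c: ExposureContribution,
    regions: RegionMap | None,
    region_id: int | None,
    region_level: str,
    season: str | None,
) -> float:
    dp = c.delta_P
    if region_id is not None:
        if regions is None:
            raise ValueError("region scope requires a region map")
        cells = regions.cells_of(region_level, region_id)
        dp = dp[:, cells]
    if season is not None:
        step_season = np.repeat(np.asarray(c.season_of_day), c.steps_per_day)
        dp = dp[step_season == season]
    return float(dp.sum())


def timing_shift_experiment(
    S: SensitivityField | Sequence[SensitivityField],
    E_daily: EmissionInventory | Sequence[EmissionInventory],
    base_kernel: DiurnalKernel,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
    regions: RegionMap | None = None,
    region_id: int | None = None,
    region_level: str = "state",
    season: str | None = None,
) -> pd.DataFrame:
    """Percent change in attributed exposure for each within-day shift.

    For each shift the daily inventory is re-disaggregated with the shifted
    kernel and re-attributed against the same sensitivities. Multiple
    (S, E) pairs stand in for multiple years; the table then reports the
    across-year mean together with the single-year extremes (the error-bar
    analog of the shift figure).
    """
    S_list = [S] if isinstance(S, SensitivityField) else list(S)
    E_list = [E_daily] if isinstance(E_daily, EmissionInventory) else list(E_daily)
    if len(S_list) != len(E_list):
        raise ValueError("need one sensitivity field per emission inventory")

    baselines = []
    for s, e in zip(S_list, E_list):
        base = _scoped_total(
            attribute(s, apply_kernel(e, base_kernel)),
            regions,
            region_id,
            region_level,
            season,
        )
        if base == 0:
            raise ValueError("scope has zero baseline attributed exposure")
        baselines.append(base)

    rows = []
    for delta in shifts:
        kernel = shift_kernel(base_kernel, delta)
        pct = []
        for s, e, base in zip(S_list, E_list, baselines):
            shifted = _scoped_total(
                attribute(s, apply_kernel(e, kernel)),
                regions,
                region_id,
                region_level,
                season,
            )
            pct.append(100.0 * (shifted - base) / base)
        pct = np.asarray(pct)
        rows.append(
            dict(
                shift_hours=int(delta),
                pct_change_mean=float(pct.mean()),
                pct_change_min=float(pct.min()),
                pct_change_max=float(pct.max()),
            )
        )
    return pd.DataFrame(rows)


def categorize_districts(
    metrics: pd.DataFrame,
    x_threshold: float = 1.3,
    y_threshold: float = 1000.0,
) -> pd.Series:
    """Two-axis district categories.

    x = emissions per production (KT MT⁻¹), y = deaths per emissions
    (deaths KT⁻¹). Ties land on the "high" side (>= threshold):

    - C1: high x, high y (priority targets)
    - C2: low x, high y
    - C3: high x, low y
    - C4: low x, low y
    """
    x = metrics["emissions_per_production"]
    y = metrics["deaths_per_emission"]
    high_x = x >= x_threshold
    high_y = y >= y_threshold
    cat = pd.Series("C4", index=metrics.index, name="category")
    cat[high_x & high_y] = "C1"
    cat[~high_x & high_y] = "C2"
    cat[high_x & ~high_y] = "C3"
    return cat


def rank_contributions(agg: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Order an aggregation table by share with cumulative shares.

    Ties are broken by key label so the ordering is deterministic.
    """
    ranked = agg.sort_values(
        ["share_percent", "key"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["cumulative_share_percent"] = ranked["share_percent"].cumsum()
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked
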