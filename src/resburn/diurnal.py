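"""Within-day triangular emission profile: build, shift, disaggregate.

The continuous profile is a symmetric triangle centered on the peak hour.
Its half-base is solved numerically so that a prescribed fraction of the
total mass (95% by default) falls inside a stated local-time window, which
need not be symmetric about the peak. Hourly weights are exact integrals of
the continuous density over each hour bin; any mass clipped at the day
boundary is redistributed by renormalization, so daily totals are conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .synthetic_world.types import EmissionInventory

__all__ = [
    "DiurnalKernel",
    "build_triangular_kernel",
    "shift_kernel",
    "apply_kernel",
    "SHIFT_RANGE",
]

#: Shift range actually evaluated by the timing experiments (hours).
SHIFT_RANGE = (-6, 1)


def _triangle_cdf(x: np.ndarray | float, peak: float, half_base: float):
    """CDF of the unit-mass symmetric triangle on [peak-b, peak+b]."""
    x = np.asarray(x, dtype=float)
    b = half_base
    lo, hi = peak - b, peak + b
    out = np.zeros_like(x)
    left = (x > lo) & (x <= peak)
    right = (x > peak) & (x < hi)
    out[left] = (x[left] - lo) ** 2 / (2.0 * b * b)
    out[right] = 1.0 - (hi - x[right]) ** 2 / (2.0 * b * b)
    out[x >= hi] = 1.0
    return out


@dataclass(frozen=True)
class DiurnalKernel:
    """24 hourly weights plus the continuous triangle they discretize."""

    weights: np.ndarray
    peak_hour: float
    window: tuple[float, float]
    half_base: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (24,):
            raise ValueError("kernel needs exactly 24 hourly weights")
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")
        if not (0.0 <= self.peak_hour < 24.0):
            raise ValueError("peak_hour must lie in [0, 24)")

    @property
    def peak_bin(self) -> int:
        """The hour bin containing the continuous peak."""
        return int(self.peak_hour)

    def _norm(self) -> float:
        """Mass of the (possibly clipped) triangle inside [0, 24)."""
        lo, hi = _triangle_cdf(np.array([0.0, 24.0]), self.peak_hour, self.half_base)
        return float(hi - lo)

    def mass_between(self, start: float, end: float) -> float:
        """Exact fraction of the kernel's mass between two local times."""
        lo = max(start, 0.0)
        hi = min(end, 24.0)
        if hi <= lo:
            return 0.0
        a, b = _triangle_cdf(np.array([lo, hi]), self.peak_hour, self.half_base)
        return float((b - a) / self._norm())

    def window_mass(self) -> float:
        """Mass inside the kernel's own window."""
        return self.mass_between(*self.window)


def _discretize(peak: float, half_base: float) -> np.ndarray:
    edges = np.arange(25, dtype=float)
    cdf = _triangle_cdf(edges, peak, half_base)
    w = np.diff(cdf)
    total = w.sum()
    if total <= 0:
        raise ValueError("kernel has no mass inside the day")
    return w / total


def build_triangular_kernel(
    peak_hour: float = 14.5,
    window: tuple[float, float] = (6.5, 19.5),
    window_mass: float = 0.95,
) -> DiurnalKernel:
    """Solve the triangle whose window captures the stated mass fraction.

    The half-base ``b`` is found with Brent's method on the (monotone
    decreasing) map from b to in-window mass.
    """
    start, end = window
    if not (0.0 <= start < peak_hour < end <= 24.0):
        raise ValueError(
            f"need 0 <= start < peak < end <= 24, got window={window}, peak={peak_hour}"
        )
    if not (0.0 < window_mass <= 1.0):
        raise ValueError(f"window_mass must lie in (0, 1], got {window_mass}")

    def in_window(b: float) -> float:
        lo, hi = _triangle_cdf(np.array([start, end]), peak_hour, b)
        return float(hi - lo)

    b_min = min(peak_hour - start, end - peak_hour)  # largest b with mass 1
    if window_mass == 1.0:
        half_base = b_min
    else:
        b_max = 200.0
        half_base = brentq(
            lambda b: in_window(b) - window_mass, b_min, b_max, xtol=1e-13, rtol=1e-15
        )
    return DiurnalKernel(
        weights=_discretize(peak_hour, half_base),
        peak_hour=peak_hour,
        window=(start, end),
        half_base=half_base,
    )


def shift_kernel(k: DiurnalKernel, delta_hours: int) -> DiurnalKernel:
    """Translate the continuous triangle by a whole number of hours.

    Mass pushed past the day boundary is clipped and the remaining weights
    renormalized, conserving daily totals. Shifts outside the evaluated
    range (-6..+1) are allowed but warned about.
    """
    if int(delta_hours) != delta_hours:
        raise ValueError(f"delta_hours must be an integer, got {delta_hours}")
    delta = int(delta_hours)
    if delta == 0:
        return k
    if not (SHIFT_RANGE[0] <= delta <= SHIFT_RANGE[1]):
        warnings.warn(
            f"shift of {delta:+d} h is outside the evaluated range "
            f"[{SHIFT_RANGE[0]}, {SHIFT_RANGE[1]}]",
            stacklevel=2,
        )
    peak = k.peak_hour + delta
    if not (0.0 <= peak < 24.0):
        raise ValueError(f"shifted peak {peak} falls outside the day")
    start = min(max(k.window[0] + delta, 0.0), peak)
    end = max(min(k.window[1] + delta, 24.0), peak)
    return DiurnalKernel(
        weights=_discretize(peak, k.half_base),
        peak_hour=peak,
        window=(start, end),
        half_base=k.half_base,
    )


def apply_kernel(
    E_daily: EmissionInventory, k: DiurnalKernel, steps_per_day: int = 24
) -> EmissionInventory:
    """Disaggregate a daily inventory to hourly using the kernel weights."""
    if E_daily.resolution != "daily":
        raise ValueError("apply_kernel expects a daily inventory")
    if len(k.weights) != steps_per_day:
        raise ValueError(
            f"kernel has {len(k.weights)} weights but the grid runs "
            f"{steps_per_day} steps per day"
        )
    n_days = E_daily.n_days
    hourly = np.einsum("dij,h->dhij", E_daily.E, k.weights).reshape(
        n_days * steps_per_day, *E_daily.E.shape[1:]
    )
    return EmissionInventory(
        E=hourly,
        resolution="hourly",
        season_of_day=E_daily.season_of_day,
        species=E_daily.species,
    )
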