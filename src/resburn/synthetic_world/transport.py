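"""Linear toy transport: forward simulation and its exact adjoint.

The one-step propagator is ``P = (1 - d) · D · A`` where ``A`` is first-order
upwind advection (lon shift then lat shift, outflow boundaries), ``D`` is a
5-point diffusion stencil with leakage at the edges, and ``d`` is the linear
deposition rate. Fresh emissions at step ``t`` enter diluted by the diurnal
mixing-depth cycle:

    chi_t = P chi_{t-1} + E_t * scale_t,
    scale_t = emission_scale / (cell_area * mixing_depth_cycle[hour(t)])

The whole map E -> chi is linear, so the sensitivity of any population-
weighted cost function to emissions is obtained exactly by running the
transposed propagator backwards in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    ConcentrationField,
    EmissionInventory,
    GridSpec,
    PopulationGrid,
    TransportConfig,
)

__all__ = ["SensitivityField", "simulate_forward", "build_adjoint", "injection_scales"]


@dataclass(frozen=True)
class SensitivityField:
    """Exposure sensitivity dJ/dE, person·µg m⁻³ per kg, per cell per step."""

    S: np.ndarray
    cost_function_tag: str = "all"

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.ndim != 3:
            raise ValueError("S must be (n_steps, n_lat, n_lon)")
        if not np.all(np.isfinite(S)):
            raise ValueError("sensitivities must be finite")


def _advect_1d(c: np.ndarray, w: float, axis: int) -> np.ndarray:
    """First-order upwind shift by ``w`` cells along ``axis``, outflow lost."""
    if w == 0:
        return c
    out = (1.0 - abs(w)) * c
    donor = np.zeros_like(c)
    if w > 0:
        src = [slice(None)] * c.ndim
        dst = [slice(None)] * c.ndim
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    else:
        src = [slice(None)] * c.ndim
        dst = [slice(None)] * c.ndim
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    donor[tuple(dst)] = abs(w) * c[tuple(src)]
    return out + donor


def _advect(c: np.ndarray, u: float, v: float) -> np.ndarray:
    """Advect in lon (axis 1, by u) then lat (axis 0, by v)."""
    return _advect_1d(_advect_1d(c, u, axis=1), v, axis=0)


def _advect_T(c: np.ndarray, u: float, v: float) -> np.ndarray:
    """Transpose of ``_advect``: reversed shifts in reversed order."""
    return _advect_1d(_advect_1d(c, -v, axis=0), -u, axis=1)


def _diffuse(c: np.ndarray, k: float) -> np.ndarray:
    """5-point diffusion; every cell sheds 4k, edge shares leak out.

    Symmetric, so it is its own transpose.
    """
    if k == 0:
        return c
    out = (1.0 - 4.0 * k) * c
    out[1:, :] += k * c[:-1, :]
    out[:-1, :] += k * c[1:, :]
    out[:, 1:] += k * c[:, :-1]
    out[:, :-1] += k * c[:, 1:]
    return out


def _propagate(c: np.ndarray, tc: TransportConfig) -> np.ndarray:
    u, v = tc.wind
    return (1.0 - tc.deposition_rate) * _diffuse(_advect(c, u, v), tc.diffusion)


def _propagate_T(c: np.ndarray, tc: TransportConfig) -> np.ndarray:
    u, v = tc.wind
    return _advect_T(_diffuse((1.0 - tc.deposition_rate) * c, tc.diffusion), u, v)


def injection_scales(tc: TransportConfig, grid: GridSpec) -> np.ndarray:
    """Per-step emission-to-concentration factors (length n_steps)."""
    hours = np.array([grid.hour_of_step(t) for t in range(grid.n_steps)])
    return tc.emission_scale / (grid.cell_area * tc.mixing_depth_cycle[hours])


def simulate_forward(
    E: EmissionInventory, tc: TransportConfig, grid: GridSpec
) -> ConcentrationField:
    """Run the linear transport model forward over all time steps.

    ``E`` must be at hourly resolution (one slab per grid time step).
    """
    if E.resolution != "hourly":
        raise ValueError(
            "simulate_forward needs hourly emissions; disaggregate the daily "
            "inventory with a diurnal kernel first"
        )
    if E.E.shape != (grid.n_steps, grid.n_lat, grid.n_lon):
        raise ValueError(
            f"emission shape {E.E.shape} does not match grid "
            f"({grid.n_steps}, {grid.n_lat}, {grid.n_lon})"
        )
    scales = injection_scales(tc, grid)
    chi = np.empty((grid.n_steps, grid.n_lat, grid.n_lon))
    c = np.zeros(grid.shape)
    for t in range(grid.n_steps):
        c = _propagate(c, tc) + E.E[t] * scales[t]
        chi[t] = c
    return ConcentrationField(chi=chi)


def build_adjoint(
    tc: TransportConfig,
    grid: GridSpec,
    pop: PopulationGrid,
    mask: np.ndarray | None = None,
    cost_function_tag: str = "all",
) -> SensitivityField:
    """Exact sensitivities of the population-exposure cost to every emission.

    Runs the transposed propagator backwards from the population weights
    (restricted to ``mask``). ``S[t, j, i]`` is the change in total
    person·µg m⁻³ caused by one extra kg emitted in cell (j, i) at step t.
    """
    rho = pop.rho
    if rho.shape != grid.shape:
        raise ValueError("population grid does not match the grid spec")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape does not match the grid")
        rho = np.where(mask, rho, 0.0)
        if rho.sum() <= 0:
            raise ValueError("mask selects zero population")
    scales = injection_scales(tc, grid)
    S = np.empty((grid.n_steps, grid.n_lat, grid.n_lon))
    w = np.zeros(grid.shape)
    for t in range(grid.n_steps - 1, -1, -1):
        w = rho + _propagate_T(w, tc) if t < grid.n_steps - 1 else rho.copy()
        S[t] = scales[t] * w
    return SensitivityField(S=S, cost_function_tag=cost_function_tag)
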