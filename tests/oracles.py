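"""Independent brute-force oracles used by the tests.

These rebuild the toy transport as explicit dense matrices from the written
definition (upwind advection, 5-point diffusion, linear deposition, diluted
injection) without touching the package's matrix-free implementation.
"""

from __future__ import annotations

import numpy as np


def idx(r: int, c: int, n_lon: int) -> int:
    return r * n_lon + c


def dense_advection(n_lat: int, n_lon: int, u: float, v: float) -> np.ndarray:
    """Dense matrix of lon-then-lat first-order upwind advection."""
    n = n_lat * n_lon
    Mx = np.zeros((n, n))
    for r in range(n_lat):
        for c in range(n_lon):
            i = idx(r, c, n_lon)
            Mx[i, i] += 1.0 - abs(u)
            if u > 0 and c > 0:
                Mx[i, idx(r, c - 1, n_lon)] += u
            elif u < 0 and c < n_lon - 1:
                Mx[i, idx(r, c + 1, n_lon)] += -u
    My = np.zeros((n, n))
    for r in range(n_lat):
        for c in range(n_lon):
            i = idx(r, c, n_lon)
            My[i, i] += 1.0 - abs(v)
            if v > 0 and r > 0:
                My[i, idx(r - 1, c, n_lon)] += v
            elif v < 0 and r < n_lat - 1:
                My[i, idx(r + 1, c, n_lon)] += -v
    return My @ Mx


def dense_diffusion(n_lat: int, n_lon: int, k: float) -> np.ndarray:
    n = n_lat * n_lon
    D = np.zeros((n, n))
    for r in range(n_lat):
        for c in range(n_lon):
            i = idx(r, c, n_lon)
            D[i, i] = 1.0 - 4.0 * k
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < n_lat and 0 <= cc < n_lon:
                    D[i, idx(rr, cc, n_lon)] += k
    return D


def dense_propagator(tc, grid) -> np.ndarray:
    """One-step propagator P = (1 - d) * D * A as a dense matrix."""
    u, v = tc.wind
    A = dense_advection(grid.n_lat, grid.n_lon, u, v)
    D = dense_diffusion(grid.n_lat, grid.n_lon, tc.diffusion)
    return (1.0 - tc.deposition_rate) * (D @ A)


def dense_forward(E: np.ndarray, tc, grid) -> np.ndarray:
    """Concentration field (n_steps, n_lat, n_lon) from dense linear algebra."""
    P = dense_propagator(tc, grid)
    n = grid.n_cells
    chi = np.zeros((grid.n_steps, n))
    c = np.zeros(n)
    for t in range(grid.n_steps):
        hour = grid.hour_of_step(t)
        scale = tc.emission_scale / (grid.cell_area * tc.mixing_depth_cycle[hour])
        c = P @ c + E[t].ravel() * scale
        chi[t] = c
    return chi.reshape(grid.n_steps, grid.n_lat, grid.n_lon)


def triangle_mass(lo: float, hi: float, peak: float, half_base: float, n: int = 2_000_001) -> float:
    """Numerically integrate the symmetric triangle density over [lo, hi]."""
    x = np.linspace(lo, hi, n)
    y = np.maximum(1.0 - np.abs(x - peak) / half_base, 0.0) / half_base
    return float(np.trapezoid(y, x))
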