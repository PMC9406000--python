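"""Independent slow oracles used to cross-check the implementation.

Deliberately naive: the bound fraction is obtained from the roots of the
mass-balance quadratic (not from the closed-form branch the package
evaluates), the Kd fit is a profiled grid search, and the contact
counter is an explicit all-pairs double loop.
"""

from __future__ import annotations

import math

import numpy as np


def bound_fraction_roots(T0: float, L0: float, kd: float) -> float:
    """Bound fraction from np.roots on T0·b² − (T0+L0+kd)·b + L0 = 0."""
    if L0 == 0:
        return 0.0
    roots = np.roots([T0, -(T0 + L0 + kd), L0])
    real = roots[np.isreal(roots)].real
    assert real.size, f"no real root for T0={T0}, L0={L0}, kd={kd}"
    return float(np.clip(real.min(), 0.0, 1.0))  # smaller root is physical


def profiled_rss(L: np.ndarray, y: np.ndarray, T0: float, kd: float) -> float:
    """RSS at the analytically profiled per-residue amplitude
    dmax = Σ b·y / Σ b² (the least-squares optimum for fixed kd)."""
    b = np.array([bound_fraction_roots(T0, float(l), kd) for l in L])
    denom = float(b @ b)
    dmax = float(b @ y) / denom if denom > 0 else 0.0
    dmax = max(dmax, 0.0)
    return float(np.sum((y - dmax * b) ** 2))


def grid_search_kd(
    L: np.ndarray,
    y: np.ndarray,
    T0: float,
    kd_lo: float = 1e-2,
    kd_hi: float = 1e3,
    n_grid: int = 200,
    refinements: int = 4,
) -> float:
    """Brute-force Kd: dense log grid, then shrinking linear grids."""
    grid = np.geomspace(kd_lo, kd_hi, n_grid)
    for _ in range(refinements + 1):
        rss = [profiled_rss(L, y, T0, kd) for kd in grid]
        i = int(np.argmin(rss))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        best = grid[i]
        grid = np.linspace(lo, hi, n_grid)
    return float(best)


def contact_fractions_double_loop(traj, cutoff: float) -> dict[int, float]:
    """Per-residue contact fraction by explicit frame/atom/ion loops."""
    n = traj.n_frames
    out = {}
    for resnum in traj.residues:
        ra = traj.residue_atoms[resnum]
        count = 0
        for f in range(n):
            hit = False
            for atom in ra.coords[f]:
                for ion in traj.ion_coords[f]:
                    d = math.dist(tuple(atom), tuple(ion))
                    if d <= cutoff:
                        hit = True
            if hit:
                count += 1
        out[resnum] = count / n
    return out
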