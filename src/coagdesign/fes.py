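"""Two-dimensional free-energy surfaces over trajectory order parameters.

A surface is the Boltzmann inversion of a binned 2D probability
distribution: F = -kT ln(P / P_max), so the global minimum sits at zero
and only relative populations matter. Typical order-parameter pairs are
(RMSD, Rg) for receptor conformational compactness and (interaction
energy, windowed TM6 RMSF) for agonist-coupled activation. Empty bins
are masked, never assigned zero free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, ValidationError
from .metrics import MetricSeries, rmsf

#: Boltzmann constant in kJ/(mol K)
KB_KJ_PER_MOL_K = 0.0083144621


@dataclass
class FESGrid:
    """Binned probability and free energy over two order parameters."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray  # (nx, ny), sums to 1 over occupied bins
    free_energy: np.ndarray  # kJ/mol; min over occupied bins is 0
    empty_mask: np.ndarray  # True where no samples fell
    kT: float

    @property
    def occupied_min(self) -> float:
        return float(self.free_energy[~self.empty_mask].min())


def free_energy_surface(x: MetricSeries, y: MetricSeries, bins=(50, 50),
                        temperature: float = 298.0,
                        x_edges=None, y_edges=None) -> FESGrid:
    """Boltzmann-inverted 2D histogram of two per-frame series.

    Bins span the observed range per axis unless explicit edges are given;
    a constant series is a degenerate-range error without explicit edges.
    kT = 0.0083144621 * T kJ/mol (2.478 at 298 K).
    """
    xv, yv = np.asarray(x.values), np.asarray(y.values)
    if xv.shape != yv.shape or xv.size < 1:
        raise ValidationError("order-parameter series must be equal-length, non-empty")
    nx, ny = bins
    if nx < 1 or ny < 1:
        raise ValidationError("need at least one bin per axis")
    if x_edges is None:
        if np.ptp(xv) == 0 and nx > 1:
            raise ValidationError(
                f"constant series {x.name!r}: provide explicit x_edges"
            )
        x_edges = np.linspace(xv.min(), xv.max() if np.ptp(xv) else xv.min() + 1.0, nx + 1)
    if y_edges is None:
        if np.ptp(yv) == 0 and ny > 1:
            raise ValidationError(
                f"constant series {y.name!r}: provide explicit y_edges"
            )
        y_edges = np.linspace(yv.min(), yv.max() if np.ptp(yv) else yv.min() + 1.0, ny + 1)

    counts, x_edges, y_edges = np.histogram2d(xv, yv, bins=[x_edges, y_edges])
    prob = counts / counts.sum()
    empty = counts == 0
    kT = KB_KJ_PER_MOL_K * temperature
    free = np.full_like(prob, np.nan)
    free[~empty] = -kT * np.log(prob[~empty] / prob.max())
    return FESGrid(x_edges, y_edges, prob, free, empty, kT)


def locate_minima(grid: FESGrid, depth: float = np.inf) -> list:
    """Occupied bins that are 4-neighbourhood local minima within *depth*
    kJ/mol of the global minimum, sorted by free energy (ties by index)."""
    nx, ny = grid.free_energy.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            if grid.empty_mask[i, j]:
                continue
            f = grid.free_energy[i, j]
            if f - grid.occupied_min > depth:
                continue
            is_min = True
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < nx and 0 <= nj < ny and not grid.empty_mask[ni, nj]:
                    if grid.free_energy[ni, nj] < f:
                        is_min = False
                        break
            if is_min:
                out.append((i, j))
    return sorted(out, key=lambda ij: (grid.free_energy[ij], ij))


def windowed_rmsf_series(traj: Trajectory, selection, window: int = 20) -> MetricSeries:
    """Per-frame RMSF order parameter: the mean RMSF of *selection* over a
    sliding window of frames centred on each frame.

    A per-frame value of a fluctuation quantity needs a convention; here
    each frame is scored by the fluctuation of its local window (clipped at
    the trajectory ends), which tracks slow changes in flexibility while
    remaining defined for every frame.
    """
    if window < 2:
        raise ValidationError("window must span >= 2 frames")
    n = traj.n_frames
    if n < 2:
        raise ValidationError("need >= 2 frames")
    half = window // 2
    vals = np.empty(n)
    for f in range(n):
        lo = max(0, f - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        sub = Trajectory(traj.topology, traj.frames[lo:hi], traj.frame_interval)
        profile = rmsf(sub, selection)
        vals[f] = float(np.mean(list(profile.values.values())))
    return MetricSeries("windowed_RMSF", vals, "A")


def grid_to_table(grid: FESGrid):
    """Long-format table (x_center, y_center, probability, free_energy)."""
    import pandas as pd

    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    rows = []
    for i, xv in enumerate(xc):
        for j, yv in enumerate(yc):
            f = grid.free_energy[i, j]
            rows.append((xv, yv, grid.probability[i, j],
                         None if grid.empty_mask[i, j] else f))
    return pd.DataFrame(rows, columns=["x", "y", "probability",
                                       "free_energy (kJ/mol)"])
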