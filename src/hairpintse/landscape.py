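"""Two-dimensional free-energy landscapes by Boltzmann inversion.

The pooled frames are binned on a 2D grid over a pair of order parameters
(default 40 x 40 = 1600 cells).  With p_i the occupancy probability of cell
i and p_ref that of the most probable cell,

    dA_i = -R T ln(p_i / p_ref)   [kJ/mol]

so the reference cell (the folded-state mode) sits at 0 and every other
occupied cell is uphill.  Unoccupied cells carry +inf and are excluded from
all statistics.

Statistical errors are estimated by recomputing dA on M disjoint subsets of
the trajectories (default M = 3 groups of two) and taking the standard error
of the subset mean: sigma_M = s / sqrt(M), with s the sample standard
deviation across subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AssignmentError, ConfigurationError, DegenerateAxisError
from .model import R_GAS, OrderParamSeries

#: Axes with a physically fixed range (fractions); others span the pooled data.
FIXED_RANGES = {"Q": (0.0, 1.0)}


@dataclass
class LandscapeGrid:
    """Binned probabilities, free energies and errors over an order-parameter plane."""

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray      # (nx, ny) integers
    probability: np.ndarray
    delta_a: np.ndarray     # kJ/mol; +inf where unoccupied
    ref_cell: tuple[int, int]
    temperature: float
    sigma: np.ndarray | None = None  # kJ/mol; NaN where unavailable

    @property
    def n_bins(self) -> int:
        return len(self.x_edges) - 1

    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell of a point; final bin is right-closed."""
        ix = int(np.searchsorted(self.x_edges, x, side="right") - 1)
        iy = int(np.searchsorted(self.y_edges, y, side="right") - 1)
        nx, ny = self.counts.shape
        if ix == nx and np.isclose(x, self.x_edges[-1]):
            ix = nx - 1
        if iy == ny and np.isclose(y, self.y_edges[-1]):
            iy = ny - 1
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise AssignmentError(
                f"point ({x}, {y}) outside the landscape axes "
                f"[{self.x_edges[0]}, {self.x_edges[-1]}] x [{self.y_edges[0]}, {self.y_edges[-1]}]"
            )
        return ix, iy

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        ix, iy = cell
        return (
            0.5 * (self.x_edges[ix] + self.x_edges[ix + 1]),
            0.5 * (self.y_edges[iy] + self.y_edges[iy + 1]),
        )


def _pooled_xy(series: list[OrderParamSeries], x: str, y: str) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([s.data[x].to_numpy() for s in series])
    ys = np.concatenate([s.data[y].to_numpy() for s in series])
    return xs, ys


def _axis_edges(name: str, values: np.ndarray, n_bins: int) -> np.ndarray:
    if name in FIXED_RANGES:
        lo, hi = FIXED_RANGES[name]
    else:
        lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateAxisError(f"axis {name!r} has zero width (all values {lo})")
    return np.linspace(lo, hi, n_bins + 1)


def _delta_a(counts: np.ndarray, ref_cell: tuple[int, int], temperature: float) -> np.ndarray:
    out = np.full(counts.shape, np.inf)
    occ = counts > 0
    n_ref = counts[ref_cell]
    if n_ref <= 0:
        return out
    out[occ] = -R_GAS * temperature * np.log(counts[occ] / n_ref)
    return out


def build_landscape(
    series: list[OrderParamSeries],
    x: str = "Q",
    y: str = "R",
    n_bins: int = 40,
    temperature: float = 300.0,
) -> LandscapeGrid:
    """Histogram the pooled series on an n_bins x n_bins grid and invert.

    The reference cell is the most probable cell (ties broken by lowest
    (x, y) bin index, for determinism).
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    if not series or sum(len(s) for s in series) == 0:
        raise ConfigurationError("no frames to bin")
    xs, ys = _pooled_xy(series, x, y)
    x_edges = _axis_edges(x, xs, n_bins)
    y_edges = _axis_edges(y, ys, n_bins)
    counts, _, _ = np.histogram2d(xs, ys, bins=[x_edges, y_edges])
    counts = counts.astype(int)
    probability = counts / counts.sum()
    # argmax over flattened C-order array = first (lowest x, then y) maximum
    ref_flat = int(np.argmax(counts))
    ref_cell = tuple(int(v) for v in np.unravel_index(ref_flat, counts.shape))
    delta_a = _delta_a(counts, ref_cell, temperature)
    return LandscapeGrid(
        x_name=x,
        y_name=y,
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        probability=probability,
        delta_a=delta_a,
        ref_cell=ref_cell,
        temperature=temperature,
    )


def subset_errors(
    series: list[OrderParamSeries],
    grouping: list[list[str]],
    grid: LandscapeGrid,
) -> np.ndarray:
    """Per-cell standard error of dA across M disjoint trajectory subsets.

    Each subset's dA is anchored to the global reference cell (its own count
    of that cell), keeping cells comparable across subsets.  A cell that any
    subset never visits (or a subset that misses the reference cell) gets
    NaN, never zero.  The result is also stored on ``grid.sigma``.
    """
    m = len(grouping)
    if m < 2:
        raise ConfigurationError(f"need M >= 2 subsets, got {m}")
    by_id = {s.traj_id: s for s in series}
    assigned = [tid for group in grouping for tid in group]
    if len(assigned) != len(set(assigned)):
        raise ConfigurationError("a trajectory appears in more than one subset")
    missing = [tid for tid in assigned if tid not in by_id]
    if missing:
        raise ConfigurationError(f"unknown trajectory ids in grouping: {missing}")

    estimates = []
    for group in grouping:
        xs, ys = _pooled_xy([by_id[t] for t in group], grid.x_name, grid.y_name)
        counts, _, _ = np.histogram2d(xs, ys, bins=[grid.x_edges, grid.y_edges])
        estimates.append(_delta_a(counts.astype(int), grid.ref_cell, grid.temperature))
    stack = np.stack(estimates)  # (M, nx, ny)
    sigma = np.full(grid.counts.shape, np.nan)
    ok = np.all(np.isfinite(stack), axis=0)
    if ok.any():
        sigma[ok] = np.std(stack[:, ok], axis=0, ddof=1) / np.sqrt(m)
    sigma[~grid.occupied()] = np.nan
    grid.sigma = sigma
    return sigma


def subset_standard_error(values: np.ndarray | list[float]) -> float:
    """sigma_M = sample standard deviation across M subset means / sqrt(M)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ConfigurationError("need >= 2 subset estimates")
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


@dataclass
class ConvergenceTrace:
    """dA estimate of one cell as a function of elapsed sampling time."""

    cell: tuple[int, int]
    elapsed_us: np.ndarray
    delta_a: np.ndarray  # NaN where the cell or reference is not yet visited


def convergence_trace(
    series: list[OrderParamSeries],
    cell: tuple[int, int],
    checkpoints_us: list[float],
    grid: LandscapeGrid,
) -> ConvergenceTrace:
    """Re-estimate one cell's dA from data truncated at growing elapsed times.

    Each trajectory is truncated at the same elapsed time (ps) before
    pooling; the grid's bin edges and reference cell are reused so estimates
    are comparable along the trace.
    """
    cps = np.asarray(checkpoints_us, dtype=float)
    if np.any(np.diff(cps) <= 0):
        raise ConfigurationError("checkpoints must be strictly increasing")
    values = np.full(len(cps), np.nan)
    for k, cp in enumerate(cps):
        t_max = cp * 1e6  # us -> ps
        xs, ys = [], []
        for s in series:
            mask = s.data["time_ps"].to_numpy() <= t_max
            xs.append(s.data[grid.x_name].to_numpy()[mask])
            ys.append(s.data[grid.y_name].to_numpy()[mask])
        xcat, ycat = np.concatenate(xs), np.concatenate(ys)
        if len(xcat) == 0:
            continue
        counts, _, _ = np.histogram2d(xcat, ycat, bins=[grid.x_edges, grid.y_edges])
        da = _delta_a(counts.astype(int), grid.ref_cell, grid.temperature)
        if np.isfinite(da[cell]):
            values[k] = da[cell]
    return ConvergenceTrace(cell=cell, elapsed_us=cps, delta_a=values)


def write_grid(grid: LandscapeGrid, csv_path: str | Path, meta_path: str | Path) -> None:
    """Serialize the grid as a per-cell CSV plus a JSON metadata sidecar."""
    nx, ny = grid.counts.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    sigma = grid.sigma if grid.sigma is not None else np.full(grid.counts.shape, np.nan)
    df = pd.DataFrame(
        {
            "x_index": ix.ravel(),
            "y_index": iy.ravel(),
            "x_center": xc[ix.ravel()],
            "y_center": yc[iy.ravel()],
            "count": grid.counts.ravel(),
            "probability": grid.probability.ravel(),
            "deltaA_kJmol": grid.delta_a.ravel(),
            "sigma_kJmol": sigma.ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "x_name": grid.x_name,
        "y_name": grid.y_name,
        "x_edges": grid.x_edges.tolist(),
        "y_edges": grid.y_edges.tolist(),
        "ref_cell": list(grid.ref_cell),
        "temperature_K": grid.temperature,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_grid(csv_path: str | Path, meta_path: str | Path) -> LandscapeGrid:
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    nx = len(meta["x_edges"]) - 1
    ny = len(meta["y_edges"]) - 1
    counts = np.zeros((nx, ny), dtype=int)
    counts[df["x_index"], df["y_index"]] = df["count"]
    sigma = np.full((nx, ny), np.nan)
    sigma[df["x_index"], df["y_index"]] = df["sigma_kJmol"]
    ref_cell = tuple(meta["ref_cell"])
    grid = LandscapeGrid(
        x_name=meta["x_name"],
        y_name=meta["y_name"],
        x_edges=np.array(meta["x_edges"]),
        y_edges=np.array(meta["y_edges"]),
        counts=counts,
        probability=counts / counts.sum(),
        delta_a=_delta_a(counts, ref_cell, meta["temperature_K"]),
        ref_cell=ref_cell,
        temperature=meta["temperature_K"],
        sigma=sigma if np.isfinite(sigma).any() else None,
    )
    return grid
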