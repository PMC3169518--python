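"""Decompose the landscape into folded (F), unfolded (U) and transition (TS) states.

The folded basin is grown by 8-connected flood fill from the global
free-energy minimum over cells within ``basin_cut`` (default 12 kJ/mol) of
it; the unfolded basin likewise from the deepest local minimum not reachable
from the folded seed through sub-cutoff cells.  Every remaining occupied
cell belongs to the transition state; frames are labeled by the cell they
fall in.

The transition-state ensemble can be refined by discarding excursions that
terminate in a "false fold": a stretch of F-labeled frames whose turn
(N6-G9 C-alpha) distance shows a clearly non-native turn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SingleBasinError, UndefinedOverlapError
from .landscape import LandscapeGrid
from .model import DistanceSeries, OrderParamSeries

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StateDefinition:
    """Seeds and depth cutoff defining the two basins."""

    f_seed: tuple[int, int]
    u_seed: tuple[int, int]
    basin_cut: float = 12.0

    def __post_init__(self):
        if self.f_seed == self.u_seed:
            raise ConfigurationError("folded and unfolded seeds coincide")
        if self.basin_cut <= 0:
            raise ConfigurationError("basin_cut must be positive")


@dataclass
class StateLabelSeries:
    """Per-frame U/TS/F labels for one trajectory."""

    traj_id: str
    times: np.ndarray
    labels: list[str]

    def __post_init__(self):
        if len(self.times) != len(self.labels):
            raise ConfigurationError("times and labels differ in length")

    def __len__(self) -> int:
        return len(self.labels)


def _flood_fill(grid: LandscapeGrid, seed: tuple[int, int], cut: float) -> set[tuple[int, int]]:
    """8-connected region of occupied cells with dA <= cut containing seed."""
    nx, ny = grid.counts.shape
    if not np.isfinite(grid.delta_a[seed]) or grid.delta_a[seed] > cut:
        return set()
    region = {seed}
    stack = [seed]
    while stack:
        cx, cy = stack.pop()
        for dx, dy in _NEIGHBORS:
            nxt = (cx + dx, cy + dy)
            if not (0 <= nxt[0] < nx and 0 <= nxt[1] < ny) or nxt in region:
                continue
            if np.isfinite(grid.delta_a[nxt]) and grid.delta_a[nxt] <= cut:
                region.add(nxt)
                stack.append(nxt)
    return region


def _local_minima(grid: LandscapeGrid) -> list[tuple[int, int]]:
    """Occupied cells whose dA is lower than all (occupied or not) 8 neighbors."""
    nx, ny = grid.counts.shape
    minima = []
    da = grid.delta_a
    for ix in range(nx):
        for iy in range(ny):
            if not np.isfinite(da[ix, iy]):
                continue
            if all(
                da[ix, iy] < da[ix + dx, iy + dy]
                for dx, dy in _NEIGHBORS
                if 0 <= ix + dx < nx and 0 <= iy + dy < ny
            ):
                minima.append((ix, iy))
    return minima


def find_basins(grid: LandscapeGrid, basin_cut: float = 12.0) -> StateDefinition:
    """Locate the folded and unfolded seeds on the landscape.

    The folded seed is the reference (most probable) cell.  The unfolded
    seed is the lowest-dA local minimum that is *not* connected to the
    folded seed through cells within basin_cut; if no such minimum exists
    the landscape is single-basin and a SingleBasinError is raised.
    """
    f_seed = grid.ref_cell
    f_region = _flood_fill(grid, f_seed, basin_cut)
    candidates = [c for c in _local_minima(grid) if c not in f_region]
    if not candidates:
        raise SingleBasinError(
            "no unfolded basin separated from the folded seed: "
            "system is not two-state in these coordinates"
        )
    u_seed = min(candidates, key=lambda c: (grid.delta_a[c], c))
    return StateDefinition(f_seed=f_seed, u_seed=u_seed, basin_cut=basin_cut)


def basin_cells(
    grid: LandscapeGrid, defn: StateDefinition
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """(F-cells, U-cells) by flood fill from the two seeds."""
    f_cells = _flood_fill(grid, defn.f_seed, defn.basin_cut)
    u_cells = _flood_fill(grid, defn.u_seed, defn.basin_cut)
    return f_cells, u_cells


def assign_states(
    grid: LandscapeGrid,
    defn: StateDefinition,
    series: OrderParamSeries,
    ts_cap: float | None = None,
) -> StateLabelSeries:
    """Label every frame of a series as U, TS or F by its grid cell.

    Occupied cells outside both basins form the TS, following the literal
    barrier-top definition.  ``ts_cap`` optionally restricts the TS to cells
    with dA <= ts_cap (a barrier-band variant); capped-out frames are
    assigned to the nearer basin seed (by cell-index distance).
    """
    f_cells, u_cells = basin_cells(grid, defn)
    if grid.delta_a[defn.f_seed] > defn.basin_cut or defn.u_seed not in u_cells:
        raise ConfigurationError("state seeds are not occupied basin cells")
    xs = series.data[grid.x_name].to_numpy()
    ys = series.data[grid.y_name].to_numpy()
    labels = []
    for x, y in zip(xs, ys):
        cell = grid.cell_of(x, y)
        if cell in f_cells:
            labels.append("F")
        elif cell in u_cells:
            labels.append("U")
        elif ts_cap is not None and grid.delta_a[cell] > ts_cap:
            df = (cell[0] - defn.f_seed[0]) ** 2 + (cell[1] - defn.f_seed[1]) ** 2
            du = (cell[0] - defn.u_seed[0]) ** 2 + (cell[1] - defn.u_seed[1]) ** 2
            labels.append("F" if df <= du else "U")
        else:
            labels.append("TS")
    return StateLabelSeries(series.traj_id, series.data["time_ps"].to_numpy(), labels)


def _runs(labels: list[str]) -> list[tuple[int, int, str]]:
    """Maximal runs as (start_index, end_index_inclusive, symbol)."""
    runs = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            runs.append((start, k - 1, labels[start]))
            start = k
    return runs


@dataclass
class RefinementReport:
    """Spans removed from the reported TSE by the false-fold refinement."""

    false_folds: list[dict] = field(default_factory=list)
    excluded_ts_spans: list[dict] = field(default_factory=list)
    excluded_ts_indices: set[int] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "false_folds": self.false_folds,
            "excluded_ts_spans": self.excluded_ts_spans,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def refine_tse(
    labels: StateLabelSeries,
    turn_series: DistanceSeries,
    turn_native_max: float = 0.8,
) -> tuple[StateLabelSeries, RefinementReport]:
    """Exclude false-folded transitions from the TSE.

    An F residence whose mean turn (N6-G9 C-alpha) distance exceeds
    ``turn_native_max`` fell into the folded region of the landscape with a
    clearly non-native turn: it is relabeled U, and the TS excursion that
    terminated in it is excluded from the reported TSE.
    """
    if len(turn_series.values) != len(labels):
        raise ConfigurationError("turn series and labels are not aligned")
    new_labels = list(labels.labels)
    report = RefinementReport()
    runs = _runs(labels.labels)
    for r, (start, end, sym) in enumerate(runs):
        if sym != "F":
            continue
        mean_turn = float(np.mean(turn_series.values[start : end + 1]))
        if mean_turn <= turn_native_max:
            continue
        for k in range(start, end + 1):
            new_labels[k] = "U"
        report.false_folds.append(
            {
                "traj_id": labels.traj_id,
                "start_ps": float(labels.times[start]),
                "end_ps": float(labels.times[end]),
                "mean_turn_nm": mean_turn,
            }
        )
        # the TS excursion terminating in this false fold leaves the TSE
        if r > 0 and runs[r - 1][2] == "TS":
            ts_start, ts_end, _ = runs[r - 1]
            report.excluded_ts_indices.update(range(ts_start, ts_end + 1))
            report.excluded_ts_spans.append(
                {
                    "traj_id": labels.traj_id,
                    "start_ps": float(labels.times[ts_start]),
                    "end_ps": float(labels.times[ts_end]),
                }
            )
    return StateLabelSeries(labels.traj_id, labels.times, new_labels), report


def tse_frames(
    labels: StateLabelSeries, report: RefinementReport | None = None
) -> list[int]:
    """Frame indices of the reported TSE (TS labels minus refined exclusions)."""
    excluded = report.excluded_ts_indices if report is not None else set()
    return [k for k, lab in enumerate(labels.labels) if lab == "TS" and k not in excluded]


def tse_overlap(
    labels_a: list[StateLabelSeries],
    labels_b: list[StateLabelSeries],
    method: str = "reference",
) -> float:
    """Fraction of the reference TSE (a) shared with an alternative TSE (b).

    ``method="reference"`` divides the intersection by |TSE_a| (the R-Q
    labeling is the reference); ``method="jaccard"`` divides by the union.
    """
    a_ts: set[tuple[str, int]] = set()
    b_ts: set[tuple[str, int]] = set()
    by_id = {s.traj_id: s for s in labels_b}
    for sa in labels_a:
        if sa.traj_id not in by_id:
            raise ConfigurationError(f"trajectory {sa.traj_id!r} missing from second labeling")
        sb = by_id[sa.traj_id]
        if len(sa) != len(sb):
            raise ConfigurationError("label series cover different frames")
        a_ts.update((sa.traj_id, k) for k, lab in enumerate(sa.labels) if lab == "TS")
        b_ts.update((sb.traj_id, k) for k, lab in enumerate(sb.labels) if lab == "TS")
    if not a_ts:
        raise UndefinedOverlapError("reference labeling has no TS frames")
    inter = len(a_ts & b_ts)
    if method == "reference":
        return inter / len(a_ts)
    if method == "jaccard":
        return inter / len(a_ts | b_ts)
    raise ConfigurationError(f"unknown overlap method {method!r}")
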