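"""Structural characterization of the TSE and of the folding mechanism.

Distance histograms over frame ensembles (TSE, folded state, per-path-class
TS subpopulations, the prior-to-TS ensemble) and aligned time courses of the
characteristic distances along reactive paths.

The five standard observables are the turn (N6-G9), middle (Y4-T12) and
end-to-end (S1-E15) C-alpha distances plus the minimum sidechain distances
of the W11 key-lock pairs W11-P7 and W11-G9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyEnsembleError
from .model import (
    END_PAIR,
    MIDDLE_PAIR,
    TURN_PAIR,
    W11_G9_PAIR,
    W11_P7_PAIR,
    DistanceSeries,
    Trajectory,
)
from .order_parameters import compute_distance_series
from .path_kinetics import PATH_CLASSES, PathSegment
from .state_assignment import StateLabelSeries

#: The five topology observables: label -> (pair, mode).
STANDARD_OBSERVABLES = {
    "turn": (TURN_PAIR, "calpha"),
    "middle": (MIDDLE_PAIR, "calpha"),
    "end": (END_PAIR, "calpha"),
    "w11_p7": (W11_P7_PAIR, "sidechain_min"),
    "w11_g9": (W11_G9_PAIR, "sidechain_min"),
}


@dataclass
class EnsembleHistogram:
    """Normalized distance histogram over one frame ensemble."""

    label: str
    observable: str
    bin_edges: np.ndarray
    densities: np.ndarray  # frequencies summing to 1
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak(self) -> float:
        """Modal bin center (nm)."""
        return float(self.bin_centers[int(np.argmax(self.densities))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center_nm": self.bin_centers, "density": self.densities})


def histogram_values(
    values: np.ndarray, bin_width: float, label: str, observable: str
) -> EnsembleHistogram:
    """Histogram raw distances on a uniform grid aligned to bin_width."""
    if len(values) == 0:
        raise EmptyEnsembleError(f"{label}/{observable}: no frames selected")
    lo = np.floor(values.min() / bin_width) * bin_width
    n = max(1, int(np.ceil((values.max() - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n + 1)
    if edges[-1] < values.max():  # guard against float round-down of the top edge
        n += 1
        edges = lo + bin_width * np.arange(n + 1)
    counts, _ = np.histogram(values, bins=edges)
    return EnsembleHistogram(
        label=label,
        observable=observable,
        bin_edges=edges,
        densities=counts / counts.sum(),
        n_frames=len(values),
    )


def ensemble_histogram(
    traj: Trajectory,
    frame_selector: list[int] | np.ndarray,
    pair: tuple[int, int],
    mode: str = "calpha",
    bin_width: float = 0.02,
    label: str = "ensemble",
) -> EnsembleHistogram:
    """Distance histogram over the selected frames of one trajectory."""
    sel = np.asarray(sorted(set(int(i) for i in frame_selector)))
    if sel.size == 0:
        raise EmptyEnsembleError("empty frame selector")
    series = compute_distance_series(traj, pair, mode)
    return histogram_values(series.values[sel], bin_width, label, f"{pair}:{mode}")


def prior_to_ts_ensemble(
    labels: StateLabelSeries,
    segments: list[PathSegment],
    window: float = 1000.0,
    frame_interval: float | None = None,
) -> list[int]:
    """Frames within ``window`` ps before TS entry along forward reactive paths.

    Union over U-TS-F segments of the frames in [start - window, start),
    clipped at the trajectory start; frames already labeled TS or F are
    excluded, so the selector is disjoint from the TSE by construction.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    if frame_interval is None:
        frame_interval = float(labels.times[1] - labels.times[0])
    forward = [s for s in segments if s.path_class == "UTSF" and s.traj_id == labels.traj_id]
    if not forward:
        raise EmptyEnsembleError("no forward reactive (U-TS-F) segments")
    n_window = int(round(window / frame_interval))
    selected: set[int] = set()
    for seg in forward:
        start = max(0, seg.start_index - n_window)
        selected.update(range(start, seg.start_index))
    return [k for k in sorted(selected) if labels.labels[k] == "U"]


def ts_frames_by_class(segments: list[PathSegment]) -> dict[str, list[int]]:
    """Pool TS frame indices of each path class (frame-wise pooling)."""
    out: dict[str, list[int]] = {cls: [] for cls in PATH_CLASSES}
    for seg in segments:
        out[seg.path_class].extend(range(seg.start_index, seg.end_index + 1))
    return out


def subpopulation_histograms(
    segments: list[PathSegment],
    traj: Trajectory,
    observables: dict[str, tuple[tuple[int, int], str]] | None = None,
    bin_width: float = 0.02,
    middle_formed_max: float = 0.6,
) -> dict:
    """Per-path-class TS histograms of the topology observables.

    Also reports, for the F-TS-F class, the fraction of TS frames whose
    middle (Y4-T12) C-alpha distance is below ``middle_formed_max`` - the
    signature of the folding-nucleus subpopulation with the central contacts
    already formed.  Classes with no segments are reported as absent (None).
    """
    observables = observables or STANDARD_OBSERVABLES
    by_class = ts_frames_by_class(segments)
    dist_cache = {
        name: compute_distance_series(traj, pair, mode)
        for name, (pair, mode) in observables.items()
    }
    result: dict = {"histograms": {}, "nucleus_fraction_ftsf": None}
    for cls in PATH_CLASSES:
        sel = np.asarray(by_class[cls], dtype=int)
        if sel.size == 0:
            result["histograms"][cls] = None
            continue
        result["histograms"][cls] = {
            name: histogram_values(ds.values[sel], bin_width, cls, name)
            for name, ds in dist_cache.items()
        }
    ftsf_sel = np.asarray(by_class["FTSF"], dtype=int)
    if ftsf_sel.size > 0 and "middle" in dist_cache:
        middle = dist_cache["middle"].values[ftsf_sel]
        result["nucleus_fraction_ftsf"] = float(np.mean(middle <= middle_formed_max))
        result["n_ftsf_ts_frames"] = int(ftsf_sel.size)
    return result


@dataclass
class TimecourseBundle:
    """Aligned observable time series around one reactive TS crossing."""

    segment: PathSegment
    times: np.ndarray           # ps, absolute trajectory time
    series: dict[str, np.ndarray]
    ts_span: tuple[float, float]  # (start_ps, end_ps) of the TS residence

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ps": self.times}
        data.update(self.series)
        df = pd.DataFrame(data)
        df["in_ts"] = (df["time_ps"] >= self.ts_span[0]) & (df["time_ps"] <= self.ts_span[1])
        return df


def reactive_timecourse(
    segments: list[PathSegment],
    traj: Trajectory,
    observables: dict[str, tuple[tuple[int, int], str]] | None = None,
    window: float = 1000.0,
    path_class: str = "UTSF",
) -> list[TimecourseBundle]:
    """Observable time courses spanning [start - window, end + window].

    One bundle per segment of ``path_class`` (forward reactive by default),
    with the TS span annotated.  An empty observable dict yields bundles
    with no series.
    """
    observables = STANDARD_OBSERVABLES if observables is None else observables
    chosen = [s for s in segments if s.path_class == path_class]
    if not chosen:
        raise EmptyEnsembleError(f"no {path_class} segments")
    dist_cache = {
        name: compute_distance_series(traj, pair, mode)
        for name, (pair, mode) in observables.items()
    }
    n_window = int(round(window / traj.frame_interval))
    bundles = []
    times = traj.times
    for seg in chosen:
        lo = max(0, seg.start_index - n_window)
        hi = min(len(traj) - 1, seg.end_index + n_window)
        sel = slice(lo, hi + 1)
        bundles.append(
            TimecourseBundle(
                segment=seg,
                times=times[sel],
                series={name: ds.values[sel] for name, ds in dist_cache.items()},
                ts_span=(seg.start_time, seg.end_time),
            )
        )
    return bundles
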