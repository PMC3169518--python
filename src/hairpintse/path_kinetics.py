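"""TS excursion segmentation, path-scenario census and lifetime kinetics.

Every maximal run of TS labels flanked by known states is one excursion,
classified by its origin and destination: U-TS-F (forward reactive),
F-TS-U (backward reactive), U-TS-U and F-TS-F (non-reactive).  The TS
lifetime tau is the time constant of a monoexponential fit to the
residence-time histogram; the commitment fraction p_fold is the fraction of
excursions exiting to the folded basin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError, InsufficientEventsError
from .landscape import subset_standard_error
from .state_assignment import StateLabelSeries, _runs

PATH_CLASSES = ("UTSF", "FTSU", "UTSU", "FTSF")


@dataclass
class PathSegment:
    """One TS excursion with its flanking states."""

    traj_id: str
    origin: str
    destination: str
    start_time: float
    end_time: float
    residence_time: float
    n_frames: int
    start_index: int
    end_index: int  # inclusive

    @property
    def path_class(self) -> str:
        return f"{self.origin}TS{self.destination}"

    @property
    def reactive(self) -> bool:
        return self.origin != self.destination


def segment_paths(labels: StateLabelSeries, frame_interval: float | None = None) -> list[PathSegment]:
    """Extract TS excursions from a label series.

    TS runs touching the trajectory boundaries are discarded (their origin
    or destination is unknown).  Residence time is n_frames * frame_interval
    (inferred from the time stamps if not given).
    """
    if len(labels) == 0:
        raise ConfigurationError("empty label series")
    if frame_interval is None:
        if len(labels.times) < 2:
            raise ConfigurationError("cannot infer frame interval from one frame")
        frame_interval = float(labels.times[1] - labels.times[0])
    runs = _runs(labels.labels)
    segments = []
    for k, (start, end, sym) in enumerate(runs):
        if sym != "TS" or k == 0 or k == len(runs) - 1:
            continue
        origin = runs[k - 1][2]
        destination = runs[k + 1][2]
        n = end - start + 1
        segments.append(
            PathSegment(
                traj_id=labels.traj_id,
                origin=origin,
                destination=destination,
                start_time=float(labels.times[start]),
                end_time=float(labels.times[end]),
                residence_time=n * frame_interval,
                n_frames=n,
                start_index=start,
                end_index=end,
            )
        )
    return segments


@dataclass
class LifetimeFit:
    """Monoexponential TS lifetime fit and commitment fractions."""

    tau: float                 # ps
    tau_error: float           # ps; NaN when no grouping was supplied
    correlation: float         # Pearson r between observed and fitted bins
    n_events: int
    p_fold: float
    p_unfold: float
    amplitude: float
    method: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _fit_tau_wls(residences: np.ndarray, frame_interval: float) -> tuple[float, float, float]:
    """Weighted least squares of ln(count) vs time on the residence histogram.

    Bin width equals the frame interval, so bin k holds the count of
    excursions lasting exactly k frames.  Poisson weighting (weight = count)
    makes the linearized fit match the histogram where it is best determined.
    Returns (tau, amplitude, correlation).
    """
    k_frames = np.rint(residences / frame_interval).astype(int)
    k_max = k_frames.max()
    counts = np.bincount(k_frames, minlength=k_max + 1)[1:]
    t = np.arange(1, k_max + 1) * frame_interval
    occupied = counts > 0
    if occupied.sum() < 2:
        raise FitError("residence histogram has a single occupied bin")
    t_o, n_o = t[occupied], counts[occupied].astype(float)
    w = n_o  # Poisson: var(ln n) ~ 1/n
    coeffs = np.polyfit(t_o, np.log(n_o), 1, w=np.sqrt(w))
    slope, intercept = coeffs[0], coeffs[1]
    if slope >= 0:
        raise FitError("residence histogram does not decay")
    tau = -1.0 / slope
    fitted = np.exp(intercept) * np.exp(-t_o / tau)
    if len(t_o) == 2:
        corr = 1.0
    else:
        corr = float(np.corrcoef(n_o, fitted)[0, 1])
    return float(tau), float(np.exp(intercept)), corr


def _fit_tau_mle(residences: np.ndarray, frame_interval: float) -> tuple[float, float, float]:
    """Geometric maximum likelihood on the raw residences.

    The per-frame survival probability is q_hat = 1 - 1/mean(k); the
    equivalent exponential time constant is -dt / ln(q_hat).
    """
    k = residences / frame_interval
    mean_k = k.mean()
    if mean_k <= 1.0:
        raise FitError("all excursions last a single frame; decay constant undefined")
    q = 1.0 - 1.0 / mean_k
    tau = -frame_interval / np.log(q)
    return float(tau), float(len(residences) * (1 - q)), 1.0


def fit_lifetime(
    segments: list[PathSegment],
    frame_interval: float,
    grouping: list[list[str]] | None = None,
    min_events: int = 20,
    method: str = "wls",
) -> LifetimeFit:
    """Fit the TS residence-time distribution and count commitment.

    ``grouping`` (M disjoint lists of traj_ids, typically 3 groups of two)
    enables the subset standard error on tau; without it tau_error is NaN.
    """
    if len(segments) < min_events:
        raise InsufficientEventsError(
            f"{len(segments)} TS excursions < required {min_events}"
        )
    residences = np.array([s.residence_time for s in segments])
    if np.allclose(residences, residences[0]):
        raise FitError("all residence times identical: degenerate histogram")
    fitter = {"wls": _fit_tau_wls, "mle": _fit_tau_mle}.get(method)
    if fitter is None:
        raise ConfigurationError(f"unknown fit method {method!r}")
    tau, amplitude, corr = fitter(residences, frame_interval)

    tau_error = float("nan")
    if grouping is not None:
        subset_taus = []
        for group in grouping:
            res_g = np.array(
                [s.residence_time for s in segments if s.traj_id in set(group)]
            )
            # a subset too small (or degenerate) to fit contributes nothing
            if len(res_g) < 2 or np.allclose(res_g, res_g[0]):
                continue
            try:
                subset_taus.append(fitter(res_g, frame_interval)[0])
            except FitError:
                continue
        if len(subset_taus) >= 2:
            tau_error = subset_standard_error(subset_taus)

    n_fold = sum(1 for s in segments if s.destination == "F")
    p_fold = n_fold / len(segments)
    return LifetimeFit(
        tau=tau,
        tau_error=tau_error,
        correlation=corr,
        n_events=len(segments),
        p_fold=p_fold,
        p_unfold=1.0 - p_fold,
        amplitude=amplitude,
        method=method,
    )


def scenario_census(segments: list[PathSegment]) -> dict:
    """Counts and mean residence time (ps) per path class."""
    out = {}
    for cls in PATH_CLASSES:
        times = [s.residence_time for s in segments if s.path_class == cls]
        out[cls] = {
            "count": len(times),
            "mean_residence_ps": float(np.mean(times)) if times else float("nan"),
        }
    out["reactive"] = out["UTSF"]["count"] + out["FTSU"]["count"]
    out["non_reactive"] = out["UTSU"]["count"] + out["FTSF"]["count"]
    return out


def write_segments(segments: list[PathSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "traj_id": [s.traj_id for s in segments],
            "class": [s.path_class for s in segments],
            "start_ps": [s.start_time for s in segments],
            "end_ps": [s.end_time for s in segments],
            "residence_ps": [s.residence_time for s in segments],
            "n_frames": [s.n_frames for s in segments],
            "start_index": [s.start_index for s in segments],
            "end_index": [s.end_index for s in segments],
        }
    )
    df.to_csv(path, index=False)


def read_segments(path: str | Path) -> list[PathSegment]:
    df = pd.read_csv(path)
    segments = []
    for row in df.itertuples():
        cls = row[2]
        segments.append(
            PathSegment(
                traj_id=str(row.traj_id),
                origin=cls[0],
                destination=cls[-1],
                start_time=float(row.start_ps),
                end_time=float(row.end_ps),
                residence_time=float(row.residence_ps),
                n_frames=int(row.n_frames),
                start_index=int(row.start_index),
                end_index=int(row.end_index),
            )
        )
    return segments
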