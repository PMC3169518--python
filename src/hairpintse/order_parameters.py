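"""Per-frame folding progress variables.

R parameter
    R = sum over the five native inter-strand C-alpha pairs of
    d_native / d_frame.  Each term tends to 1 as the pair reaches its native
    separation, so R ~ 5 signals the native hairpin; the expanded unfolded
    coil sits near R ~ 2.

Q (fraction of native sidechain contacts)
    Fraction of the native contact list whose minimum sidechain heavy-atom
    distance in the frame is within the contact cutoff (0.55 nm).

RMSD
    C-alpha root-mean-square deviation from the native conformation after
    optimal rigid-body superposition (Kabsch).

Distances are plain Euclidean distances: input coordinates are expected to
be whole-molecule (no periodic imaging is applied).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateGeometryError, StructureError
from .model import (
    NATIVE_PAIRS,
    DistanceSeries,
    Frame,
    OrderParamSeries,
    ReferenceStructure,
    Trajectory,
)


def compute_R(frame: Frame, ref: ReferenceStructure) -> float:
    """R order parameter: sum of native/instantaneous distance ratios."""
    total = 0.0
    for (i, j), d_nat in ref.native_pair_distances.items():
        d = float(np.linalg.norm(frame.ca(i) - frame.ca(j)))
        if d <= 0.0:
            raise DegenerateGeometryError(f"pair ({i},{j}) has zero distance in frame")
        total += d_nat / d
    return total


def _min_sidechain_distance(frame: Frame, i: int, j: int) -> float:
    a = frame.sidechain(i)
    b = frame.sidechain(j)
    return float(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).min())


def compute_Q(frame: Frame, ref: ReferenceStructure, contact_cutoff: float | None = None) -> float:
    """Fraction of native sidechain contacts formed in the frame."""
    if not ref.native_contacts:
        raise ConfigurationError("reference has an empty native contact list")
    cutoff = ref.contact_cutoff if contact_cutoff is None else contact_cutoff
    formed = sum(
        1 for (i, j) in ref.native_contacts if _min_sidechain_distance(frame, i, j) <= cutoff
    )
    return formed / len(ref.native_contacts)


def kabsch_rmsd(mobile: np.ndarray, target: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two (n, 3) point sets, optionally after optimal fit."""
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise DegenerateGeometryError("need matching point sets with >= 3 points")
    if superpose:
        x = mobile - mobile.mean(axis=0)
        y = target - target.mean(axis=0)
        if np.linalg.matrix_rank(np.cov(x.T)) < 2:
            raise DegenerateGeometryError("collinear point set: superposition ill-defined")
        cov = x.T @ y
        u, _, vt = np.linalg.svd(cov)
        sign = np.sign(np.linalg.det(u @ vt))
        d = np.diag([1.0, 1.0, sign])
        rot = u @ d @ vt
        x = x @ rot
    else:
        x, y = mobile, target
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def compute_rmsd(frame: Frame, ref: ReferenceStructure, superpose: bool = True) -> float:
    """C-alpha RMSD (nm) of the frame against the native reference."""
    residues = sorted(set(frame.residue_indices()) & set(ref.frame.residue_indices()))
    mobile = np.array([frame.ca(r) for r in residues])
    target = np.array([ref.frame.ca(r) for r in residues])
    return kabsch_rmsd(mobile, target, superpose=superpose)


def compute_series(
    traj: Trajectory,
    ref: ReferenceStructure,
    contact_cutoff: float | None = None,
    with_rmsd: bool = False,
) -> OrderParamSeries:
    """Vectorized per-frame (time, R, Q[, RMSD]) for a whole trajectory."""
    if not ref.native_contacts:
        raise ConfigurationError("reference has an empty native contact list")
    cutoff = ref.contact_cutoff if contact_cutoff is None else contact_cutoff
    times = traj.times

    # R: pull each pair's C-alpha track once
    r_total = np.zeros(len(traj))
    for (i, j), d_nat in ref.native_pair_distances.items():
        ca = traj.ca_array([i, j])
        d = np.linalg.norm(ca[:, 0, :] - ca[:, 1, :], axis=1)
        if np.any(d <= 0.0):
            raise DegenerateGeometryError(f"pair ({i},{j}) has zero distance")
        r_total += d_nat / d

    # Q: minimum cross sidechain distance per native contact, all frames at once
    formed = np.zeros(len(traj))
    for (i, j) in ref.native_contacts:
        a = traj.sidechain_arrays(i)
        b = traj.sidechain_arrays(j)
        d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1).min(axis=(1, 2))
        formed += d <= cutoff
    q = formed / len(ref.native_contacts)

    data = {"time_ps": times, "R": r_total, "Q": q}
    if with_rmsd:
        residues = sorted(ref.frame.residue_indices())
        target = np.array([ref.frame.ca(r) for r in residues])
        mobile = traj.ca_array(residues)
        data["RMSD"] = np.array([kabsch_rmsd(m, target) for m in mobile])
    return OrderParamSeries(traj.traj_id, pd.DataFrame(data))


def compute_distance(frame: Frame, pair: tuple[int, int], mode: str = "calpha") -> float:
    """Distance (nm) for one residue pair in one frame."""
    i, j = pair
    if mode == "calpha":
        return float(np.linalg.norm(frame.ca(i) - frame.ca(j)))
    if mode == "sidechain_min":
        return _min_sidechain_distance(frame, i, j)
    raise ConfigurationError(f"unknown distance mode {mode!r}")


def compute_distance_series(
    traj: Trajectory, pair: tuple[int, int], mode: str = "calpha"
) -> DistanceSeries:
    """Per-frame distance series for a residue pair (calpha or sidechain_min)."""
    i, j = pair
    if mode == "calpha":
        ca = traj.ca_array([i, j])
        values = np.linalg.norm(ca[:, 0, :] - ca[:, 1, :], axis=1)
    elif mode == "sidechain_min":
        a = traj.sidechain_arrays(i)
        b = traj.sidechain_arrays(j)
        values = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1).min(axis=(1, 2))
    else:
        raise ConfigurationError(f"unknown distance mode {mode!r}")
    return DistanceSeries(traj.traj_id, pair, mode, traj.times, values)
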