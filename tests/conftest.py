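"""Shared fixtures: small synthetic datasets and toy structures.

Everything is generated at test time from fixed seeds; there are no stored
data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from hairpintse.model import AtomRecord, Frame, Trajectory
from hairpintse.synthetic import (
    GeneratorConfig,
    emit_coordinates,
    emit_series_only,
    native_reference,
    simulate_states,
    template_frame,
)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    """Default-geometry generator at a small desk scale."""
    return GeneratorConfig(seed=0, duration_us=0.05)


@pytest.fixture(scope="session")
def reference(gen_config):
    """ReferenceStructure from the noiseless native template."""
    return native_reference(gen_config)


@pytest.fixture(scope="session")
def native_frame(gen_config):
    return template_frame("native", gen_config)


@pytest.fixture(scope="session")
def small_truth(gen_config):
    return simulate_states(gen_config)


@pytest.fixture(scope="session")
def small_series(small_truth, gen_config):
    """Fast-path (Q, R) series: 6 x 5000 frames."""
    return emit_series_only(small_truth, gen_config)


@pytest.fixture(scope="session")
def coordinate_data(gen_config, small_truth):
    """Toy-geometry trajectories plus the derived native reference."""
    trajs, ref = emit_coordinates(small_truth, gen_config)
    return trajs, ref


@pytest.fixture(scope="session")
def groups():
    """The standard 3 subsets of two trajectories."""
    return [["traj1", "traj2"], ["traj3", "traj4"], ["traj5", "traj6"]]


def chain_frame(positions: np.ndarray, time: float = 0.0, sidechains: bool = False) -> Frame:
    """Build a poly-ALA C-alpha frame (optionally +CB at z+0.2) from (n,3) nm."""
    atoms = []
    for i, xyz in enumerate(positions, start=1):
        atoms.append(AtomRecord(i, "ALA", "CA", np.asarray(xyz, dtype=float)))
        if sidechains:
            atoms.append(AtomRecord(i, "ALA", "CB", np.asarray(xyz, dtype=float) + [0, 0, 0.2]))
    return Frame(time=time, atoms=atoms)


def extended_chain(n: int = 15, spacing: float = 0.38) -> np.ndarray:
    """Straight C-alpha trace: every long-range pair far beyond any cutoff."""
    pts = np.zeros((n, 3))
    pts[:, 0] = spacing * np.arange(n)
    return pts


def make_trajectory(frames: list[Frame], dt: float = 10.0, traj_id: str = "t") -> Trajectory:
    for k, f in enumerate(frames):
        f.time = k * dt
    return Trajectory(traj_id, frames, dt)
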