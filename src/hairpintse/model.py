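"""Shared data model: atoms, frames, trajectories and the native reference.

All coordinates are stored in nanometres.  The system of interest is
Peptide 1, a designed 15-residue beta-hairpin (sequence SESYINPDGTWTVTE)
with an NPDG type-I turn, but nothing below is hard-wired to it beyond the
identity of the five native inter-strand C-alpha pairs used by the R order
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, StructureError

#: Ideal gas constant in kJ/(mol K).
R_GAS = 0.008314

#: One-letter sequence of Peptide 1.
PEPTIDE1_SEQUENCE = "SESYINPDGTWTVTE"

#: The five native inter-strand C-alpha pairs of the hairpin
#: (N6-T10, I5-W11, Y4-T12, S3-V13, E2-T14), 1-based residue indices.
NATIVE_PAIRS: tuple[tuple[int, int], ...] = ((6, 10), (5, 11), (4, 12), (3, 13), (2, 14))

#: Characteristic C-alpha pairs used for the topology analysis.
TURN_PAIR = (6, 9)    # N6-G9
MIDDLE_PAIR = (4, 12)  # Y4-T12
END_PAIR = (1, 15)    # S1-E15

#: Key-lock sidechain pairs: W11 against the turn residues P7 and G9.
W11_P7_PAIR = (11, 7)
W11_G9_PAIR = (11, 9)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class AtomRecord:
    """One atom: 1-based residue index, residue/atom names, coords in nm."""

    residue_index: int
    residue_name: str
    atom_name: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite 3-vector")

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOMS


@dataclass
class Frame:
    """One conformation: a time stamp (ps) and an ordered atom list."""

    time: float
    atoms: list[AtomRecord]

    def ca(self, residue_index: int) -> np.ndarray:
        """C-alpha coordinates of a residue; StructureError if absent."""
        for a in self.atoms:
            if a.residue_index == residue_index and a.atom_name == "CA":
                return a.coords
        raise StructureError(f"residue {residue_index} has no CA atom")

    def sidechain(self, residue_index: int) -> np.ndarray:
        """Sidechain heavy-atom coordinates, shape (n, 3).

        Non-backbone atoms of the residue; hydrogens (names starting with H)
        are excluded.  Glycine, which has no heavy sidechain atom, falls back
        to its C-alpha so that minimum-sidechain-distance observables (the
        W11-G9 key-lock analysis in particular) stay defined.
        """
        found_residue = False
        coords = []
        for a in self.atoms:
            if a.residue_index != residue_index:
                continue
            found_residue = True
            if a.is_backbone or a.atom_name.startswith("H"):
                continue
            coords.append(a.coords)
        if coords:
            return np.array(coords)
        if not found_residue:
            raise StructureError(f"residue {residue_index} not present in frame")
        return self.ca(residue_index)[None, :]

    def residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames at a constant sampling interval (ps)."""

    traj_id: str
    frames: list[Frame]
    frame_interval: float

    def __post_init__(self):
        if len(self.frames) < 2:
            raise EmptyInputError(
                f"trajectory {self.traj_id!r} has {len(self.frames)} frame(s); need >= 2"
            )
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.allclose(np.diff(times), self.frame_interval, atol=1e-6):
            raise ValueError("frame spacing must equal frame_interval")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack, built once and cached.

        Valid because atom ordering is identical across frames.
        """
        cached = getattr(self, "_coords", None)
        if cached is None:
            cached = np.array([[a.coords for a in f.atoms] for f in self.frames])
            object.__setattr__(self, "_coords", cached)
        return cached

    def ca_array(self, residues: list[int]) -> np.ndarray:
        """(n_frames, len(residues), 3) array of C-alpha coordinates."""
        index: dict[int, int] = {}
        for k, a in enumerate(self.frames[0].atoms):
            if a.atom_name == "CA":
                index[a.residue_index] = k
        missing = [r for r in residues if r not in index]
        if missing:
            raise StructureError(f"residues {missing} have no CA atom")
        cols = [index[r] for r in residues]
        return self.coords_array()[:, cols, :]

    def sidechain_arrays(self, residue_index: int) -> np.ndarray:
        """(n_frames, n_sidechain_atoms, 3) heavy sidechain coordinates."""
        rows = [
            k
            for k, a in enumerate(self.frames[0].atoms)
            if a.residue_index == residue_index
            and not a.is_backbone
            and not a.atom_name.startswith("H")
        ]
        if not rows:
            # glycine proxy: the C-alpha stands in for the absent sidechain
            rows = [
                k
                for k, a in enumerate(self.frames[0].atoms)
                if a.residue_index == residue_index and a.atom_name == "CA"
            ]
        if not rows:
            raise StructureError(f"residue {residue_index} not present in trajectory")
        return self.coords_array()[:, rows, :]


@dataclass
class ReferenceStructure:
    """Native conformation plus the derived native geometry.

    native_pair_distances maps each of the five inter-strand C-alpha pairs to
    its native distance (nm); native_contacts is the set of residue pairs
    whose minimum sidechain heavy-atom distance in the native frame is within
    the contact cutoff, at sequence separation >= min_separation.
    """

    frame: Frame
    native_pair_distances: dict[tuple[int, int], float]
    native_contacts: set[tuple[int, int]] = field(default_factory=set)
    contact_cutoff: float = 0.55
    min_separation: int = 3


@dataclass
class OrderParamSeries:
    """Per-frame order parameters of one trajectory.

    ``data`` is a pandas DataFrame with columns time_ps, R, Q and optionally
    RMSD (nm).
    """

    traj_id: str
    data: "pandas.DataFrame"  # noqa: F821 - imported lazily by users

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DistanceSeries:
    """Per-frame distance (nm) for one residue pair of one trajectory."""

    traj_id: str
    pair: tuple[int, int]
    mode: str  # "calpha" or "sidechain_min"
    times: np.ndarray
    values: np.ndarray
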