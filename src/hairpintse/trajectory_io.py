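"""Structure / trajectory / table input-output.

Trajectories travel as multi-model PDB files (one MODEL per saved frame);
order-parameter tables as plain CSV.  PDB files are in Angstrom as the format
requires; everything in memory is nanometres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, FormatError, ParseError, StructureError
from .model import (
    NATIVE_PAIRS,
    AtomRecord,
    Frame,
    OrderParamSeries,
    ReferenceStructure,
    Trajectory,
)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record at line {lineno}: {line!r}") from exc
    # PDB is in Angstrom; internal unit is nm
    return AtomRecord(residue_index, residue_name, atom_name, np.array([x, y, z]) / 10.0)


def read_pdb_frames(path: str | Path) -> list[Frame]:
    """Read every MODEL of a multi-model PDB as a Frame (times left at 0)."""
    frames: list[Frame] = []
    current: list[AtomRecord] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise FormatError(f"ENDMDL without MODEL at line {lineno}")
                frames.append(Frame(time=0.0, atoms=current))
                current = None
            elif rec == "ATOM" or rec == "HETATM":
                atom = _parse_atom_line(line, lineno)
                if current is None:
                    if saw_model:
                        raise FormatError(f"ATOM outside MODEL at line {lineno}")
                    current = []
                current.append(atom)
    if current is not None and not saw_model:
        # single-model file without MODEL/ENDMDL bookkeeping
        frames.append(Frame(time=0.0, atoms=current))
    if not frames:
        raise EmptyInputError(f"{path}: no models found")
    n0 = len(frames[0].atoms)
    for k, fr in enumerate(frames):
        if len(fr.atoms) != n0:
            raise FormatError(
                f"{path}: model {k + 1} has {len(fr.atoms)} atoms, expected {n0}"
            )
    return frames


def read_pdb_trajectory(
    path: str | Path, frame_interval: float, traj_id: str | None = None
) -> Trajectory:
    """Read a multi-model PDB as a trajectory sampled every frame_interval ps.

    Times are assigned 0, dt, 2*dt, ... in model order.  Raises
    EmptyInputError for fewer than two models and FormatError if the models
    do not share one atom ordering.
    """
    frames = read_pdb_frames(path)
    if len(frames) < 2:
        raise EmptyInputError(f"{path}: a trajectory needs >= 2 models, found {len(frames)}")
    for k, fr in enumerate(frames):
        fr.time = k * frame_interval
    return Trajectory(traj_id or Path(path).stem, frames, frame_interval)


def read_reference_pdb(path: str | Path) -> Frame:
    """Read a single-conformation PDB (first model if several)."""
    return read_pdb_frames(path)[0]


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:^4s} {resname:>3s} A{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
)


def _format_atom(serial: int, atom: AtomRecord) -> str:
    name = atom.atom_name
    # conventional PDB alignment: short names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    xyz = atom.coords * 10.0  # nm -> Angstrom
    return _PDB_ATOM.format(
        serial=serial,
        name=name_field,
        resname=atom.residue_name,
        resseq=atom.residue_index,
        x=xyz[0],
        y=xyz[1],
        z=xyz[2],
    )


def write_pdb_frames(frames: list[Frame], path: str | Path) -> None:
    """Write frames as a multi-model PDB (coordinates nm -> Angstrom)."""
    with open(path, "w") as fh:
        for m, fr in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            for serial, atom in enumerate(fr.atoms, start=1):
                fh.write(_format_atom(serial, atom))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    write_pdb_frames(traj.frames, path)


def _min_sidechain_distance(frame: Frame, i: int, j: int) -> float:
    a = frame.sidechain(i)
    b = frame.sidechain(j)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def build_reference(
    frame: Frame, contact_cutoff: float = 0.55, min_separation: int = 3
) -> ReferenceStructure:
    """Derive the native reference geometry from a native conformation.

    Fills the five native inter-strand C-alpha distances and the native
    sidechain contact list: every residue pair at sequence separation
    >= min_separation whose minimum sidechain heavy-atom distance is within
    contact_cutoff (nm).  Glycine uses its C-alpha as sidechain proxy.
    """
    pair_distances: dict[tuple[int, int], float] = {}
    for (i, j) in NATIVE_PAIRS:
        d = float(np.linalg.norm(frame.ca(i) - frame.ca(j)))
        if d <= 0:
            raise StructureError(f"native pair ({i},{j}) has non-positive distance")
        pair_distances[(i, j)] = d
    residues = sorted(frame.residue_indices())
    contacts: set[tuple[int, int]] = set()
    for a_idx, i in enumerate(residues):
        for j in residues[a_idx + 1 :]:
            if j - i < min_separation:
                continue
            if _min_sidechain_distance(frame, i, j) <= contact_cutoff:
                contacts.add((i, j))
    return ReferenceStructure(
        frame=frame,
        native_pair_distances=pair_distances,
        native_contacts=contacts,
        contact_cutoff=contact_cutoff,
        min_separation=min_separation,
    )


def write_reference_summary(ref: ReferenceStructure, path: str | Path) -> None:
    """JSON summary: the five native distances and the contact list."""
    payload = {
        "native_pair_distances_nm": {
            f"{i}-{j}": d for (i, j), d in sorted(ref.native_pair_distances.items())
        },
        "native_contacts": sorted(list(p) for p in ref.native_contacts),
        "contact_cutoff_nm": ref.contact_cutoff,
        "min_separation": ref.min_separation,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


SERIES_COLUMNS = ("time_ps", "R", "Q")


def write_series(series: OrderParamSeries, path: str | Path) -> None:
    """Write an order-parameter series as CSV (time_ps,R,Q[,RMSD])."""
    series.data.to_csv(path, index=False, float_format="%.6f")


def read_series(path: str | Path, traj_id: str | None = None) -> OrderParamSeries:
    """Read a series CSV; ParseError (with line number) on malformed rows."""
    with open(path) as fh:
        header = fh.readline().strip()
        columns = header.split(",")
        if columns[: len(SERIES_COLUMNS)] != list(SERIES_COLUMNS):
            raise ParseError(f"unexpected header {header!r}", line=1)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != len(columns):
                raise ParseError(f"expected {len(columns)} fields, got {len(parts)}", line=lineno)
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise ParseError(f"non-numeric value in {line.strip()!r}", line=lineno)
    data = pd.DataFrame(rows, columns=columns)
    return OrderParamSeries(traj_id or Path(path).stem, data)


def write_labels(times: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame({"time_ps": times, "label": labels}).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing 'label' column", line=1)
    bad = ~df["label"].isin(["U", "TS", "F"])
    if bad.any():
        raise ParseError(f"{path}: unknown state label", line=int(bad.idxmax()) + 2)
    return df["time_ps"].to_numpy(), df["label"].tolist()
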