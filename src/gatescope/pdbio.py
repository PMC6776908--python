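"""Readers and writers: fixed-column PDB (single and multi-model) and
plain per-frame XYZ text.

Multi-model PDB is the required trajectory container; XYZ
(``N`` / comment / ``element x y z`` per frame) is the lightweight
alternative.  Coordinates are written with three decimals (0.001 A), the
PDB column precision, and round trip at that precision.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np

from .model import AtomRecord, Structure, Trajectory, TopologyMismatchError, infer_element

__all__ = [
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory_pdb",
    "read_xyz_frames",
    "write_xyz",
]


class PDBParseError(ValueError):
    """Malformed PDB record; the message carries the 1-based line number."""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from None
    name = line[12:16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        residue_id = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from None
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed coordinate field {line[30:54]!r}"
        ) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, residue_name)
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_id=residue_id, chain_id=chain_id, position=np.array([x, y, z]),
    )


def read_pdb(path: str | os.PathLike, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path:
        File with fixed-column ATOM/HETATM records, optionally grouped in
        MODEL/ENDMDL blocks.
    model_policy:
        ``"first"`` returns a single :class:`Structure` (the first model);
        ``"all"`` returns a list of Structures, one per model.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_records = False
    label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_records = True
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
                if model_policy == "first" and models:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    structures = [
        Structure(atoms=atoms, label=f"{label}" if len(models) == 1 else f"{label}#{i+1}")
        for i, atoms in enumerate(models) if atoms
    ]
    if model_policy == "first":
        return structures[0]
    return structures


def _format_atom_line(a: AtomRecord, serial: int, bfactor: float = 0.0) -> str:
    # PDB v3.3 name justification: names shorter than 4 chars start in
    # column 14 unless they begin with a 2-letter element symbol.
    name = a.name
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name} {a.residue_name:<3s} {a.chain_id:1s}"
        f"{a.residue_id:>4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          {a.element.upper():>2s}\n"
    )


def write_pdb(
    structure: Structure,
    path: str | os.PathLike,
    bfactors: Sequence[float] | None = None,
) -> None:
    """Write a single-model PDB.  ``bfactors`` (per atom) fill the B column."""
    if bfactors is not None and len(bfactors) != len(structure):
        raise ValueError("bfactors must have one value per atom")
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms):
            b = 0.0 if bfactors is None else float(bfactors[i])
            fh.write(_format_atom_line(a, serial=i + 1, bfactor=b))
        fh.write("END\n")


def write_trajectory_pdb(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            coords = traj.frames[f]
            for i, a in enumerate(traj.topology.atoms):
                rec = AtomRecord(
                    serial=i + 1, name=a.name, element=a.element,
                    residue_name=a.residue_name, residue_id=a.residue_id,
                    chain_id=a.chain_id, position=coords[i], mass=a.mass,
                )
                fh.write(_format_atom_line(rec, serial=i + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_xyz_frames(path: str | os.PathLike) -> list[list[tuple[str, np.ndarray]]]:
    """Read a plain XYZ file into per-frame lists of (element, position)."""
    frames: list[list[tuple[str, np.ndarray]]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise PDBParseError(
                f"line {pos + 1}: expected atom count, got {lines[pos]!r}"
            ) from None
        if pos + 1 + n >= len(lines) + 1:
            raise PDBParseError(f"line {pos + 1}: truncated XYZ frame")
        frame: list[tuple[str, np.ndarray]] = []
        for k in range(n):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise PDBParseError(f"line {pos + 3 + k}: malformed XYZ atom line")
            frame.append((parts[0], np.array([float(p) for p in parts[1:4]])))
        frames.append(frame)
        pos += 2 + n
    if not frames:
        raise PDBParseError(f"no frames found in {path}")
    return frames


def write_xyz(traj: Trajectory, path: str | os.PathLike, comment: str = "") -> None:
    with open(path, "w") as fh:
        n = traj.n_atoms
        for f in range(traj.n_frames):
            fh.write(f"{n}\n{comment or f'frame {f}'}\n")
            for i, a in enumerate(traj.topology.atoms):
                x, y, z = traj.frames[f, i]
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(
    path: str | os.PathLike,
    topology: Structure,
    frame_spacing: float = 200.0,
    replica_id: int = 0,
) -> Trajectory:
    """Read a trajectory from multi-model PDB or XYZ text.

    The format is chosen by extension (``.xyz`` vs anything else = PDB).
    Every frame must carry exactly ``len(topology)`` atoms; a mismatch
    raises :class:`TopologyMismatchError` naming the offending frame.
    """
    n = len(topology)
    spath = os.fspath(path)
    if spath.lower().endswith(".xyz"):
        raw = read_xyz_frames(path)
        for f, frame in enumerate(raw):
            if len(frame) != n:
                raise TopologyMismatchError(
                    f"frame {f}: {len(frame)} atoms, topology has {n}"
                )
        frames = np.array([[pos for _, pos in frame] for frame in raw])
    else:
        models = read_pdb(path, model_policy="all")
        for f, m in enumerate(models):
            if len(m) != n:
                raise TopologyMismatchError(
                    f"frame {f}: {len(m)} atoms, topology has {n}"
                )
        frames = np.array([m.coords for m in models])
    return Trajectory(
        topology=topology, frames=frames,
        frame_spacing=frame_spacing, replica_id=replica_id,
    )
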