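"""Core data model: atoms, structures, trajectories, and helix declarations.

Coordinates are in angstroms throughout.  Residue numbering follows the
author (PDB) numbering of the input file and is never renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "HelixSpec",
    "infer_element",
    "mass_of",
    "TopologyMismatchError",
]

# Standard atomic weights (amu) for elements that occur in protein/lipid
# models.  Mass lookup is by upper-case element symbol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546,
    "ZN": 65.38, "SE": 78.971, "X": 12.011,
}

# Two-letter element symbols that may appear in PDB atom names; needed to
# disambiguate e.g. "CA" (alpha carbon) from calcium when the element
# column is blank.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "MN", "FE", "CO", "NI", "CU", "ZN", "SE"}


class TopologyMismatchError(ValueError):
    """Raised when trajectory frames disagree with the topology atom count."""


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the element from a PDB atom name (v3.3 convention).

    The element is the first alphabetic character of the justified atom
    name, except for genuine two-letter symbols (halogens, metals).  Atom
    names such as ``CA``/``CB`` inside amino-acid residues are carbon; the
    name ``CA`` in an ion residue (``CA`` residue name) is calcium.
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    # digit prefixes like 1HB2
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"atom name {atom_name!r} has no element characters")
    if stripped[:2] in _TWO_LETTER and residue_name.strip().upper() == stripped[:2]:
        return stripped[:2]
    if stripped[:2] in _TWO_LETTER and stripped[:2] not in ("CA",):
        # CL, NA, ... as leading pair only count when not a common organic
        # name pattern such as "CLA"? Keep it simple: two-letter symbols
        # other than CA are taken at face value.
        return stripped[:2]
    return stripped[0]


def mass_of(element: str) -> float:
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None


@dataclass
class AtomRecord:
    """One atom: identity plus a single position."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom serial {self.serial}")
        if not self.element:
            self.element = infer_element(self.name, self.residue_name)
        if self.mass <= 0.0:
            self.mass = mass_of(self.element)


@dataclass
class Structure:
    """An ordered list of atoms forming one conformation."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.label!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """A new Structure with the same topology and replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, label=self.label if label is None else label)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_id) pairs."""
        keys: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_id)
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys


@dataclass
class Trajectory:
    """A topology plus F frames of per-atom coordinates.

    ``frame_spacing`` is metadata only (time between saved frames, ps).
    """

    topology: Structure
    frames: np.ndarray
    frame_spacing: float = 200.0
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be an F x N x 3 array")
        if self.frames.shape[0] < 1:
            raise TopologyMismatchError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """Materialize frame ``i`` as a Structure."""
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class HelixSpec:
    """A declared alpha-helix: a chain and an inclusive residue range.

    The range must contain at least 8 residues so that the two terminal
    4-residue turns used as axis endpoints do not overlap.
    """

    label: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.last_residue - self.first_residue < 7:
            raise ValueError(
                f"helix {self.label!r}: needs >= 8 residues "
                f"({self.first_residue}-{self.last_residue} given)"
            )
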