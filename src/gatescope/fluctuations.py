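"""Root-mean-square fluctuations (RMSF): per-atom mobility about the mean.

Frames are first superposed onto the iteratively converged average
conformation (over the fit selection), then per atom i

    RMSF_i = sqrt( mean_f | r_i(f) - <r_i> |^2 )

Residue-level values are the arithmetic mean over the residue's analysed
atoms; replica-level aggregation reports mean and SEM over replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Structure, Trajectory
from .selection import Selection, resolve_selection
from .superpose import average_structure, kabsch_fit, apply_fit, superpose_frames

__all__ = ["RMSFProfile", "rmsf", "pool_rmsf"]


class InsufficientFramesError(ValueError):
    pass


@dataclass
class RMSFProfile:
    """Per-atom and per-residue RMSF for one trajectory (or a replica mean)."""

    residue_keys: list[tuple[str, int]]
    atom_indices: np.ndarray
    atom_rmsf: np.ndarray
    residue_rmsf: np.ndarray
    n_atoms_per_residue: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.atom_rmsf < 0) or np.any(self.residue_rmsf < 0):
            raise ValueError("RMSF values must be non-negative")


def _residue_aggregate(
    structure: Structure, atom_indices: np.ndarray, atom_rmsf: np.ndarray
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    keys: list[tuple[str, int]] = []
    sums: dict[tuple[str, int], list[float]] = {}
    for idx, val in zip(atom_indices, atom_rmsf):
        a = structure.atoms[int(idx)]
        k = (a.chain_id, a.residue_id)
        if k not in sums:
            sums[k] = []
            keys.append(k)
        sums[k].append(float(val))
    res = np.array([np.mean(sums[k]) for k in keys])
    counts = np.array([len(sums[k]) for k in keys])
    return keys, res, counts


def rmsf(
    traj: Trajectory,
    fit_selection: Selection | str,
    analysis_selection: Selection | str,
    reference: str = "average",
) -> RMSFProfile:
    """RMSF of the analysis atoms after superposition on the fit atoms.

    ``reference='average'`` (default) fits frames onto the converged
    average structure; ``reference='first'`` is a cheaper single-pass fit
    to frame 0.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    top = traj.topology
    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(top, fit_selection)
    if isinstance(analysis_selection, str):
        analysis_selection = resolve_selection(top, analysis_selection)
    if len(analysis_selection) == 0:
        raise ValueError("analysis selection matches no atoms")
    if reference == "average":
        ref_coords = average_structure(traj, fit_selection).coords
    elif reference == "first":
        ref_coords = traj.frames[0]
    else:
        raise ValueError("reference must be 'average' or 'first'")
    fitted = superpose_frames(traj.frames, ref_coords, fit_selection)
    idx = analysis_selection.index_array
    sub = fitted[:, idx, :]
    mean = sub.mean(axis=0)
    atom_rmsf = np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))
    keys, res_rmsf, counts = _residue_aggregate(top, idx, atom_rmsf)
    return RMSFProfile(
        residue_keys=keys, atom_indices=idx, atom_rmsf=atom_rmsf,
        residue_rmsf=res_rmsf, n_atoms_per_residue=counts,
    )


def pool_rmsf(profiles: list[RMSFProfile]) -> tuple[RMSFProfile, np.ndarray]:
    """Mean profile over replicas plus per-residue SEM (sd/sqrt(n), ddof=1).

    All profiles must share the atom set (same topology and selections).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    base = profiles[0]
    for p in profiles[1:]:
        if p.residue_keys != base.residue_keys or not np.array_equal(
            p.atom_indices, base.atom_indices
        ):
            raise ValueError("profiles do not share an atom set")
    atom = np.array([p.atom_rmsf for p in profiles])
    res = np.array([p.residue_rmsf for p in profiles])
    n = len(profiles)
    sem = res.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else np.zeros(res.shape[1])
    pooled = RMSFProfile(
        residue_keys=base.residue_keys,
        atom_indices=base.atom_indices,
        atom_rmsf=atom.mean(axis=0),
        residue_rmsf=res.mean(axis=0),
        n_atoms_per_residue=base.n_atoms_per_residue,
    )
    return pooled, sem
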