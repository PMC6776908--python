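"""Least-squares rigid-body superposition and derived analyses.

The fit is the classic SVD-based (Kabsch) solution restricted to proper
rotations: the sign of the smallest singular vector pair is corrected so
that det(R) = +1, never a reflection.  Fitting is unweighted over the
selected atoms by default (equal weights), with optional mass weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Structure, Trajectory
from .selection import Selection, resolve_selection

__all__ = [
    "DegenerateGeometryError",
    "FitResult",
    "DisplacementField",
    "kabsch_fit",
    "apply_fit",
    "superpose_frames",
    "average_structure",
    "displacement_field",
]

log = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Fit set is collinear or otherwise rank-deficient."""


@dataclass(frozen=True)
class FitResult:
    """A proper rigid transform mapping mobile onto reference.

    Fitted coordinates are ``(mobile @ rotation.T) + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass
class DisplacementField:
    """Per-residue C-alpha displacement vectors between two states."""

    residue_keys: list[tuple[str, int]]
    vectors: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if not np.allclose(self.magnitudes, np.linalg.norm(self.vectors, axis=1)):
            raise ValueError("magnitudes inconsistent with vectors")


def _check_rank(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    # rank < 2 means all points on a line (or a single point)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError(
            "fit set is collinear or degenerate; need >= 3 non-collinear points"
        )


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Selection | np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    ``fit_indices`` restricts the fit to a subset of atoms (the transform
    still applies to all).  ``weights`` (optional, e.g. masses) weight the
    least-squares problem; default is unweighted.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is not None:
        idx = fit_indices.index_array if isinstance(fit_indices, Selection) else np.asarray(fit_indices)
        m = mobile[idx]
        r = reference[idx]
        w = None if weights is None else np.asarray(weights, dtype=float)[idx]
    else:
        m, r, w = mobile, reference, weights
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("mobile and reference fit sets must both be K x 3")
    if m.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 fit atoms")
    _check_rank(m)
    _check_rank(r)
    if w is None:
        w = np.ones(m.shape[0])
    w = w / w.sum()
    mc = (w[:, None] * m).sum(axis=0)
    rc = (w[:, None] * r).sum(axis=0)
    m0 = m - mc
    r0 = r - rc
    h = (w[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt((w * ((fitted - r) ** 2).sum(axis=1)).sum()))
    return FitResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_fit(fit: FitResult, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ fit.rotation.T + fit.translation


def superpose_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_indices: Selection | np.ndarray | None = None,
) -> np.ndarray:
    """Fit every frame of an F x N x 3 stack onto ``reference``.

    Vectorized over frames (batched SVD), equivalent to calling
    :func:`kabsch_fit` per frame with unweighted fitting.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is not None:
        idx = fit_indices.index_array if isinstance(fit_indices, Selection) else np.asarray(fit_indices)
        m = frames[:, idx, :]
        r = reference[idx]
    else:
        m, r = frames, reference
    mc = m.mean(axis=1)
    rc = r.mean(axis=0)
    h = np.einsum("fki,kj->fij", m - mc[:, None, :], r - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", vt, u)))
    vt[:, 2, :] *= d[:, None]
    rot = np.einsum("fji,fkj->fik", vt, u)  # vt.T @ u.T per frame
    trans = rc[None, :] - np.einsum("fij,fj->fi", rot, mc)
    return np.einsum("fij,fnj->fni", rot, frames) + trans[:, None, :]


def average_structure(
    traj: Trajectory,
    fit_selection: Selection | str | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> Structure:
    """Iteratively converged average conformation.

    Frames are fitted to the running average on ``fit_selection``, the mean
    recomputed, until the mean per-atom coordinate change drops below
    ``tol`` (angstroms) or ``max_iter`` is reached (warning logged; the
    last average is returned).
    """
    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(traj.topology, fit_selection)
    avg = traj.frames[0].astype(float)
    if traj.n_frames == 1:
        return traj.topology.with_coords(avg, label="average")
    for _ in range(max_iter):
        fitted = superpose_frames(traj.frames, avg, fit_selection)
        new_avg = fitted.mean(axis=0)
        delta = float(np.linalg.norm(new_avg - avg, axis=1).mean())
        avg = new_avg
        if delta < tol:
            break
    else:
        log.warning(
            "average_structure: not converged after %d iterations (last change %.2e A)",
            max_iter, delta,
        )
    return traj.topology.with_coords(avg, label="average")


def displacement_field(
    state_a: Structure,
    state_b: Structure,
    fit_selection: Selection | str,
    report_selection: Selection | str,
    chain_map: dict[str, str] | None = None,
) -> DisplacementField:
    """Per-residue C-alpha displacement of ``state_b`` relative to ``state_a``.

    ``state_b`` is first rigid-fitted onto ``state_a`` over the C-alpha
    atoms of ``fit_selection`` residues (matched by chain and residue id;
    ``chain_map`` maps state_a chain ids to state_b chain ids for
    correspondence across different entries).  Vectors point a -> b.
    Residues missing from either state are skipped and logged.
    """
    cmap = chain_map or {}

    def b_chain(chain_a: str) -> str:
        return cmap.get(chain_a, chain_a)

    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(state_a, fit_selection)
    if isinstance(report_selection, str):
        report_selection = resolve_selection(state_a, report_selection)

    ca_a = {
        (a.chain_id, a.residue_id): a.position
        for a in state_a.atoms if a.name.upper() == "CA"
    }
    ca_b = {
        (a.chain_id, a.residue_id): a.position
        for a in state_b.atoms if a.name.upper() == "CA"
    }

    def residues_of(sel: Selection) -> list[tuple[str, int]]:
        keys: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for i in sel.indices:
            a = state_a.atoms[i]
            k = (a.chain_id, a.residue_id)
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    fit_keys = [
        k for k in residues_of(fit_selection)
        if k in ca_a and (b_chain(k[0]), k[1]) in ca_b
    ]
    if len(fit_keys) < 3:
        raise ValueError("no (or too few) common residues between the two states")
    a_fit = np.array([ca_a[k] for k in fit_keys])
    b_fit = np.array([ca_b[(b_chain(k[0]), k[1])] for k in fit_keys])
    fit = kabsch_fit(b_fit, a_fit)

    keys: list[tuple[str, int]] = []
    vecs: list[np.ndarray] = []
    for k in residues_of(report_selection):
        kb = (b_chain(k[0]), k[1])
        if k not in ca_a or kb not in ca_b:
            log.info("displacement_field: residue %s missing in one state; skipped", k)
            continue
        fitted_b = apply_fit(fit, ca_b[kb][None, :])[0]
        keys.append(k)
        vecs.append(fitted_b - ca_a[k])
    if not keys:
        raise ValueError("no common residues in report selection")
    vectors = np.array(vecs)
    return DisplacementField(
        residue_keys=keys, vectors=vectors,
        magnitudes=np.linalg.norm(vectors, axis=1),
    )
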