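"""Cartesian PCA (essential dynamics) and Boltzmann-inverted free-energy
landscapes.

Pooled trajectory frames are superposed onto the overall average over the
fit selection; the covariance of the analysis atoms' Cartesian
coordinates is eigendecomposed.  Projections onto the first two
components are binned in 2D, and each occupied bin i is assigned a
configurational free energy

    dG_conf,i = -R T ln(N_i / N_max)        [kcal/mol]

so the most populated bin sits at exactly zero and empty bins are
undefined (stored as +inf, serialized as the token ``inf``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Structure, Trajectory
from .selection import Selection, resolve_selection
from .superpose import average_structure, kabsch_fit, apply_fit, superpose_frames

__all__ = [
    "R_KCAL",
    "PCAModel",
    "FreeEnergyLandscape",
    "fit_pca",
    "project",
    "project_frames",
    "landscape",
    "locate_conformation",
    "representative_conformation",
    "pc_displacement_vectors",
]

# Universal gas constant in kcal / (mol K)
R_KCAL = 1.9872036e-3


@dataclass
class PCAModel:
    """Mean and orthonormal eigenbasis of the coordinate covariance.

    ``mean_coords`` is the 3M flattened mean of the superposed analysis
    atoms; eigenvalues (A^2) are sorted descending.  The fit context
    (reference coordinates and fit indices over the full topology) is kept
    so new structures can be superposed consistently before projection.
    """

    mean_coords: np.ndarray
    eigenvectors: np.ndarray  # (n_components, 3M), rows orthonormal
    eigenvalues: np.ndarray
    analysis_indices: np.ndarray
    fit_indices: np.ndarray
    reference_coords: np.ndarray  # full-topology reference for superposition

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")

    @property
    def explained_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


@dataclass
class FreeEnergyLandscape:
    """2D binned free-energy surface over (PC1, PC2).

    ``delta_g`` is +inf on unoccupied bins; the minimum over occupied bins
    is exactly 0 (the most populated bin).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray
    temperature: float = 300.0
    gas_constant: float = R_KCAL

    def __post_init__(self) -> None:
        occupied = self.counts > 0
        if occupied.any():
            dg = self.delta_g[occupied]
            if not np.isclose(dg.min(), 0.0):
                raise ValueError("occupied-bin minimum of delta_g must be 0")
            if np.any(dg < 0):
                raise ValueError("delta_g must be non-negative")
        if not np.all(np.isinf(self.delta_g[~occupied])):
            raise ValueError("unoccupied bins must be undefined (inf)")

    @property
    def n_max(self) -> int:
        return int(self.counts.max())

    def bin_of(self, point: np.ndarray) -> tuple[int, int, bool]:
        """(ix, iy, inside) for a 2D projection; outside points are clamped
        to the nearest bin and flagged ``inside=False``."""
        x, y = float(point[0]), float(point[1])
        inside = (
            self.x_edges[0] <= x <= self.x_edges[-1]
            and self.y_edges[0] <= y <= self.y_edges[-1]
        )
        ix = int(np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                         0, len(self.x_edges) - 2))
        iy = int(np.clip(np.searchsorted(self.y_edges, y, side="right") - 1,
                         0, len(self.y_edges) - 2))
        return ix, iy, inside


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive."""
    out = vectors.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_pca(
    trajectories: Sequence[Trajectory],
    fit_selection: Selection | str,
    analysis_selection: Selection | str,
) -> PCAModel:
    """PCA of pooled, superposed frames.

    All replicas are pooled; every frame is fitted onto the overall
    average conformation over ``fit_selection``; the covariance of the
    ``analysis_selection`` coordinates is eigendecomposed (via SVD of the
    centered data matrix).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    top = trajectories[0].topology
    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(top, fit_selection)
    if isinstance(analysis_selection, str):
        analysis_selection = resolve_selection(top, analysis_selection)
    pooled = np.concatenate([t.frames for t in trajectories], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames for PCA")
    pooled_traj = Trajectory(topology=top, frames=pooled)
    ref = average_structure(pooled_traj, fit_selection).coords
    fitted = superpose_frames(pooled, ref, fit_selection)
    idx = analysis_selection.index_array
    data = fitted[:, idx, :].reshape(pooled.shape[0], -1)
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD of the data matrix: eigenvalues of the covariance are s^2 / F
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = (s ** 2) / centered.shape[0]
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = _fix_signs(vt[order])
    return PCAModel(
        mean_coords=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        analysis_indices=idx,
        fit_indices=fit_selection.index_array,
        reference_coords=ref,
    )


def _superpose_to_model(frames: np.ndarray, model: PCAModel) -> np.ndarray:
    return superpose_frames(frames, model.reference_coords, model.fit_indices)


def project_frames(frames: np.ndarray, model: PCAModel, k: int = 2) -> np.ndarray:
    """Project full-topology frames (F x N x 3) onto the first k components."""
    if k > model.eigenvectors.shape[0]:
        raise ValueError(
            f"k={k} exceeds available components ({model.eigenvectors.shape[0]})"
        )
    fitted = _superpose_to_model(np.asarray(frames, dtype=float), model)
    data = fitted[:, model.analysis_indices, :].reshape(frames.shape[0], -1)
    return (data - model.mean_coords) @ model.eigenvectors[:k].T


def project(traj: Trajectory, model: PCAModel, k: int = 2) -> np.ndarray:
    """Per-frame k-vector of PC coordinates for a trajectory."""
    return project_frames(traj.frames, model, k=k)


def landscape(
    projections: np.ndarray,
    bins: int | tuple[int, int] | tuple[np.ndarray, np.ndarray] = 100,
    temperature: float = 300.0,
    pad_fraction: float = 0.02,
) -> FreeEnergyLandscape:
    """Boltzmann-inverted 2D free-energy surface from (PC1, PC2) points."""
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("projections must be F x >=2")
    if pts.shape[0] < 1:
        raise ValueError("need at least one projected frame")
    x, y = pts[:, 0], pts[:, 1]

    def _edges(vals: np.ndarray, n: int) -> np.ndarray:
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo
        if span == 0.0:
            span = max(abs(hi), 1.0)
        return np.linspace(lo - pad_fraction * span, hi + pad_fraction * span, n + 1)

    if isinstance(bins, (int, np.integer)):
        edges = (_edges(x, int(bins)), _edges(y, int(bins)))
    elif isinstance(bins[0], (int, np.integer)):
        edges = (_edges(x, int(bins[0])), _edges(y, int(bins[1])))
    else:
        edges = (np.asarray(bins[0], dtype=float), np.asarray(bins[1], dtype=float))
    counts, xe, ye = np.histogram2d(x, y, bins=edges)
    n_max = counts.max()
    delta_g = np.full_like(counts, np.inf)
    occ = counts > 0
    delta_g[occ] = -R_KCAL * temperature * np.log(counts[occ] / n_max)
    # guard against -0.0 and tiny negatives from rounding
    delta_g[occ] = np.maximum(delta_g[occ], 0.0)
    return FreeEnergyLandscape(
        x_edges=xe, y_edges=ye, counts=counts, delta_g=delta_g,
        temperature=temperature,
    )


def locate_conformation(
    structure: Structure,
    model: PCAModel,
    fel: FreeEnergyLandscape,
) -> tuple[float, bool]:
    """Free energy (kcal/mol) of the landscape bin containing ``structure``.

    The structure is superposed and projected like a trajectory frame.
    Returns ``(delta_g, inside)``; a projection outside the landscape is
    flagged ``inside=False`` and the nearest bin's value is reported.
    """
    if len(structure) != model.reference_coords.shape[0]:
        raise ValueError(
            "structure does not match the model topology "
            f"({len(structure)} vs {model.reference_coords.shape[0]} atoms)"
        )
    proj = project_frames(structure.coords[None, :, :], model, k=2)[0]
    ix, iy, inside = fel.bin_of(proj)
    return float(fel.delta_g[ix, iy]), inside


def representative_conformation(
    trajectories: Sequence[Trajectory],
    model: PCAModel,
    fel: FreeEnergyLandscape,
) -> tuple[int, int]:
    """(replica position, frame index) of the representative conformation.

    The representative frame is the one whose (PC1, PC2) lies nearest (in
    Euclidean distance) to the center of the most populated bin; ties are
    broken by lowest (replica, frame).
    """
    imax = np.unravel_index(np.argmax(fel.counts), fel.counts.shape)
    cx = 0.5 * (fel.x_edges[imax[0]] + fel.x_edges[imax[0] + 1])
    cy = 0.5 * (fel.y_edges[imax[1]] + fel.y_edges[imax[1] + 1])
    best: tuple[float, int, int] | None = None
    for r, traj in enumerate(trajectories):
        proj = project(traj, model, k=2)
        d = np.hypot(proj[:, 0] - cx, proj[:, 1] - cy)
        f = int(np.argmin(d))
        cand = (float(d[f]), r, f)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best[1], best[2]


def basin_delta_g(
    pc1: np.ndarray, temperature: float = 300.0, max_iter: int = 100
) -> float:
    """Free-energy difference (kcal/mol) between two basins along PC1.

    Frames are split into two clusters by a 1D two-means (Lloyd) threshold
    on their PC1 coordinate; the difference is -R T ln(n_minor / n_major).
    Intended for clearly bimodal projections (two-state systems).
    """
    x = np.sort(np.asarray(pc1, dtype=float))
    thr = 0.5 * (x[0] + x[-1])
    for _ in range(max_iter):
        left = x[x < thr]
        right = x[x >= thr]
        if len(left) == 0 or len(right) == 0:
            break
        new_thr = 0.5 * (left.mean() + right.mean())
        if abs(new_thr - thr) < 1e-12:
            break
        thr = new_thr
    n_a = max((x < thr).sum(), (x >= thr).sum())
    n_b = min((x < thr).sum(), (x >= thr).sum())
    if n_b == 0:
        raise ValueError("projections are not bimodal: one cluster is empty")
    return float(-R_KCAL * temperature * np.log(n_b / n_a))


def pc_displacement_vectors(
    model: PCAModel,
    component: int = 0,
    scale: float = 1.0,
    cutoff: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom displacement arrows along one principal component.

    Each analysis atom's 3-vector from the eigenvector is multiplied by
    ``scale * sqrt(eigenvalue)`` (the mode's RMS amplitude); arrows with
    magnitude below ``cutoff`` (A) are omitted.  Returns (atom indices
    into the topology, arrow vectors).
    """
    if not 0 <= component < model.eigenvectors.shape[0]:
        raise ValueError(f"component {component} out of range")
    vecs = model.eigenvectors[component].reshape(-1, 3) * (
        scale * np.sqrt(model.eigenvalues[component])
    )
    mags = np.linalg.norm(vecs, axis=1)
    keep = mags >= cutoff
    return model.analysis_indices[keep], vecs[keep]
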