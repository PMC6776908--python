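"""Protein-frame-aligned 3D occupancy densities for lipid atom classes.

Every frame is rigid-fitted onto a protein reference (the fit selection's
average conformation) before the selected particles are binned on a
regular grid.  Voxel values are occupancy counts summed over frames and
divided by the number of frames, i.e. mean per-frame occupancy — no
voxel-volume or bulk normalization — so replicating frames leaves the
grid exactly unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from gridData import Grid

from .model import Trajectory
from .selection import Selection, resolve_selection
from .superpose import average_structure, superpose_frames

__all__ = ["DensityGrid", "density_grid", "write_dx", "read_dx"]

log = logging.getLogger(__name__)


@dataclass
class DensityGrid:
    """Regular 3D grid of mean per-frame particle occupancy."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    class_label: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D voxel array")
        if np.any(self.values < 0):
            raise ValueError("occupancy values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_center(self, ijk: tuple[int, int, int]) -> np.ndarray:
        return self.origin + (np.asarray(ijk, dtype=float) + 0.5) * self.spacing


def density_grid(
    traj: Trajectory,
    particle_selection: Selection | str,
    fit_selection: Selection | str | None = None,
    spacing: float = 1.0,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
    pad: float = 15.0,
    class_label: str = "",
) -> DensityGrid:
    """Mean per-frame occupancy grid of the selected particles.

    ``extent`` is an (origin, upper-corner) pair; by default it is the
    bounding box of the fitted fit-selection atoms padded by ``pad`` A.
    Particles landing outside the extent are counted and logged, never an
    error.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    top = traj.topology
    if isinstance(particle_selection, str):
        particle_selection = resolve_selection(top, particle_selection)
    if len(particle_selection) == 0:
        raise ValueError("particle selection matches no atoms")
    frames = traj.frames
    if fit_selection is not None:
        if isinstance(fit_selection, str):
            fit_selection = resolve_selection(top, fit_selection)
        ref = average_structure(traj, fit_selection).coords
        frames = superpose_frames(frames, ref, fit_selection)
        box_source = ref[fit_selection.index_array]
    else:
        box_source = frames[0][particle_selection.index_array]
    if extent is None:
        lo = box_source.min(axis=0) - pad
        hi = box_source.max(axis=0) + pad
    else:
        lo = np.asarray(extent[0], dtype=float)
        hi = np.asarray(extent[1], dtype=float)
    nvox = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    edges = [lo[d] + spacing * np.arange(nvox[d] + 1) for d in range(3)]
    pts = frames[:, particle_selection.index_array, :].reshape(-1, 3)
    counts, _ = np.histogramdd(pts, bins=edges)
    n_outside = pts.shape[0] - int(counts.sum())
    if n_outside:
        log.info("density_grid: %d particle positions fell outside the extent", n_outside)
    values = counts / traj.n_frames
    return DensityGrid(origin=lo, spacing=spacing, values=values, class_label=class_label)


def write_dx(grid: DensityGrid, path: str) -> None:
    """Write the grid as an OpenDX scalar field (plain text)."""
    g = Grid(
        grid.values,
        origin=grid.origin + 0.5 * grid.spacing,  # gridData uses voxel centers
        delta=[grid.spacing] * 3,
    )
    g.export(str(path), file_format="dx")


def read_dx(path: str, class_label: str = "") -> DensityGrid:
    """Read an OpenDX scalar field back into a DensityGrid."""
    g = Grid(str(path))
    delta = np.asarray(g.delta)
    spacing = float(delta[0]) if delta.ndim == 1 else float(delta[0, 0])
    origin = np.asarray(g.origin, dtype=float) - 0.5 * spacing
    return DensityGrid(
        origin=origin, spacing=spacing, values=np.asarray(g.grid),
        class_label=class_label,
    )
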