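"""Lateral-gate geometry descriptors.

Three families of observables characterize the gate between the N- and
C-terminal halves of the translocon:

* distances between mass-weighted centers of mass (COM) of 4-residue
  helical turns on opposing helices (distances I-IV);
* the inter-helix angle eta between two helix axes, each axis drawn from
  the backbone COM of a helix's first four residues to that of its last
  four (N -> C orientation);
* helix (or helical-hairpin) tilt against a membrane normal, folded into
  [0, 90] degrees.

Per-replica time series are summarized as histograms of relative
frequencies with the mean and standard error over replicas per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import HelixSpec, Structure, Trajectory
from .selection import BACKBONE_NAMES, Selection, resolve_selection

__all__ = [
    "TurnSpec",
    "GatePairSpec",
    "GateGeometrySeries",
    "SpecResolutionError",
    "turn_com",
    "pair_distance_series",
    "helix_vector",
    "eta_angle",
    "eta_series",
    "helix_tilt",
    "membrane_normal",
    "gate_series",
    "replica_histogram",
]


class SpecResolutionError(ValueError):
    """A turn or helix declaration does not resolve on the structure."""


@dataclass(frozen=True)
class TurnSpec:
    """Four consecutive residues forming one helical turn."""

    chain_id: str
    residues: tuple[int, int, int, int]
    atom_class: str = "all"  # all | backbone | calpha

    def __post_init__(self) -> None:
        res = tuple(self.residues)
        if len(res) != 4 or any(b - a != 1 for a, b in zip(res, res[1:])):
            raise ValueError(f"turn residues must be 4 consecutive ids, got {res}")
        object.__setattr__(self, "residues", res)
        if self.atom_class not in ("all", "backbone", "calpha"):
            raise ValueError(f"unknown atom_class {self.atom_class!r}")


@dataclass(frozen=True)
class GatePairSpec:
    """A labelled COM-COM distance between two helical turns."""

    label: str
    turn_a: TurnSpec
    turn_b: TurnSpec

    def __post_init__(self) -> None:
        if self.turn_a == self.turn_b:
            raise ValueError("turn_a and turn_b must differ")


@dataclass
class GateGeometrySeries:
    """Per-replica gate descriptor series plus pooled histogram summaries.

    ``distances[label]`` is a list (one entry per replica) of per-frame
    distance arrays (A); ``eta`` likewise in degrees.  ``histograms`` maps
    each observable to (bin_edges, per_replica_freqs, mean_freq, sem),
    where relative frequencies per replica sum to 1 and the SEM is
    sd/sqrt(n) over replicas.  ``start_values`` holds the frame-0 value of
    replica 0 (the "starting structure" reference line).
    """

    distances: dict[str, list[np.ndarray]]
    eta: list[np.ndarray]
    histograms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    start_values: dict[str, float]
    replica_ids: list[int] = field(default_factory=list)


def _turn_indices(structure: Structure, spec: TurnSpec) -> np.ndarray:
    sel: list[int] = []
    present: set[int] = set()
    for i, a in enumerate(structure.atoms):
        if a.chain_id != spec.chain_id or a.residue_id not in spec.residues:
            continue
        present.add(a.residue_id)
        name = a.name.upper()
        if spec.atom_class == "calpha" and name != "CA":
            continue
        if spec.atom_class == "backbone" and name not in BACKBONE_NAMES:
            continue
        sel.append(i)
    missing = set(spec.residues) - present
    if missing:
        raise SpecResolutionError(
            f"turn {spec.chain_id}:{spec.residues}: residue(s) "
            f"{sorted(missing)} not found"
        )
    if not sel:
        raise SpecResolutionError(
            f"turn {spec.chain_id}:{spec.residues}: no atoms of class "
            f"{spec.atom_class!r}"
        )
    return np.asarray(sel, dtype=int)


def turn_com(
    frame: np.ndarray, structure: Structure, spec: TurnSpec
) -> np.ndarray:
    """Mass-weighted center of the turn's selected atoms in ``frame``."""
    idx = _turn_indices(structure, spec)
    masses = structure.masses[idx]
    coords = np.asarray(frame, dtype=float)[idx]
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def pair_distance_series(traj: Trajectory, pair: GatePairSpec) -> np.ndarray:
    """Euclidean COM-COM distance (A) per frame."""
    ia = _turn_indices(traj.topology, pair.turn_a)
    ib = _turn_indices(traj.topology, pair.turn_b)
    ma = traj.topology.masses[ia]
    mb = traj.topology.masses[ib]
    coma = (ma[None, :, None] * traj.frames[:, ia]).sum(axis=1) / ma.sum()
    comb = (mb[None, :, None] * traj.frames[:, ib]).sum(axis=1) / mb.sum()
    return np.linalg.norm(coma - comb, axis=1)


def _terminal_turns(helix: HelixSpec) -> tuple[TurnSpec, TurnSpec]:
    first = TurnSpec(
        chain_id=helix.chain_id,
        residues=tuple(range(helix.first_residue, helix.first_residue + 4)),
        atom_class="backbone",
    )
    last = TurnSpec(
        chain_id=helix.chain_id,
        residues=tuple(range(helix.last_residue - 3, helix.last_residue + 1)),
        atom_class="backbone",
    )
    return first, last


def helix_vector(
    frame: np.ndarray, structure: Structure, helix: HelixSpec
) -> np.ndarray:
    """Unit axis vector of a helix, oriented N -> C.

    Drawn from the backbone COM of the first four residues to the backbone
    COM of the last four.
    """
    first, last = _terminal_turns(helix)
    v = turn_com(frame, structure, last) - turn_com(frame, structure, first)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise SpecResolutionError(f"helix {helix.label!r}: zero-length axis")
    return v / norm


def eta_angle(
    frame: np.ndarray,
    structure: Structure,
    helix7: HelixSpec,
    helix8: HelixSpec,
) -> float:
    """Angle (degrees, in [0, 180]) between the two helix axis vectors."""
    v7 = helix_vector(frame, structure, helix7)
    v8 = helix_vector(frame, structure, helix8)
    return float(np.degrees(np.arccos(np.clip(v7 @ v8, -1.0, 1.0))))


def eta_series(
    traj: Trajectory, helix7: HelixSpec, helix8: HelixSpec
) -> np.ndarray:
    return np.array([
        eta_angle(traj.frames[f], traj.topology, helix7, helix8)
        for f in range(traj.n_frames)
    ])


def helix_tilt(
    structure: Structure,
    helix_or_hairpin: HelixSpec | Sequence[HelixSpec],
    normal: np.ndarray,
) -> float:
    """Tilt (degrees, folded into [0, 90]) of a helix or hairpin axis
    against ``normal``.

    For a hairpin (two antiparallel helices) the shared long axis is
    (v1 - v2) normalized; a near-parallel pair given as a hairpin is a
    degeneracy error.
    """
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("normal must be nonzero")
    normal = normal / nn
    frame = structure.coords
    if isinstance(helix_or_hairpin, HelixSpec):
        axis = helix_vector(frame, structure, helix_or_hairpin)
    else:
        helices = list(helix_or_hairpin)
        if len(helices) != 2:
            raise ValueError("hairpin requires exactly two helices")
        v1 = helix_vector(frame, structure, helices[0])
        v2 = helix_vector(frame, structure, helices[1])
        combined = v1 - v2
        norm = np.linalg.norm(combined)
        if norm < 0.5:  # antiparallel pair gives |v1-v2| ~ 2
            raise SpecResolutionError(
                "hairpin axis degenerate: the two helices are near-parallel"
            )
        axis = combined / norm
    cosang = abs(float(axis @ normal))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def interstate_helix_tilt(
    state_a: Structure,
    state_b: Structure,
    helix: HelixSpec,
    fit_selection,
    chain_map: dict[str, str] | None = None,
) -> float:
    """Tilt change (degrees) of one helix between two states.

    ``state_b`` is rigid-fitted onto ``state_a`` over the C-alpha atoms of
    ``fit_selection`` residues (matched by chain and residue id through
    ``chain_map``), then the angle between the helix's axis vectors in the
    two aligned states is returned.  ``helix`` is declared on state_a
    chains; its chain id is mapped for state_b.
    """
    from dataclasses import replace as _replace

    from .superpose import apply_fit, displacement_field, kabsch_fit

    cmap = chain_map or {}
    # reuse the displacement-field correspondence to obtain the fit
    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(state_a, fit_selection)
    ca_a = {(a.chain_id, a.residue_id): a.position
            for a in state_a.atoms if a.name.upper() == "CA"}
    ca_b = {(a.chain_id, a.residue_id): a.position
            for a in state_b.atoms if a.name.upper() == "CA"}
    keys = []
    seen: set[tuple[str, int]] = set()
    for i in fit_selection.indices:
        a = state_a.atoms[i]
        k = (a.chain_id, a.residue_id)
        kb = (cmap.get(k[0], k[0]), k[1])
        if k not in seen and k in ca_a and kb in ca_b:
            seen.add(k)
            keys.append((k, kb))
    if len(keys) < 3:
        raise SpecResolutionError("too few common CA atoms in fit selection")
    a_fit = np.array([ca_a[k] for k, _ in keys])
    b_fit = np.array([ca_b[kb] for _, kb in keys])
    fit = kabsch_fit(b_fit, a_fit)
    v_a = helix_vector(state_a.coords, state_a, helix)
    helix_b = _replace(helix, chain_id=cmap.get(helix.chain_id, helix.chain_id))
    v_b_raw = helix_vector(state_b.coords, state_b, helix_b)
    v_b = fit.rotation @ v_b_raw
    return float(np.degrees(np.arccos(np.clip(abs(v_a @ v_b), 0.0, 1.0))))


def membrane_normal(structure: Structure, bundle_selection: Selection | str) -> np.ndarray:
    """Estimate the membrane normal from a transmembrane helix bundle.

    Convention: the first principal axis (largest variance) of the
    C-alpha inertia of the bundle — TM helices run roughly along the
    normal, so their pooled C-alpha spread is largest along it.  The sign
    is unspecified; callers orient it via their chain map if needed.
    """
    if isinstance(bundle_selection, str):
        bundle_selection = resolve_selection(structure, bundle_selection)
    idx = [
        i for i in bundle_selection.indices
        if structure.atoms[i].name.upper() == "CA"
    ]
    if len(idx) < 3:
        raise SpecResolutionError("bundle selection must contain >= 3 CA atoms")
    coords = structure.coords[idx]
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def replica_histogram(
    series: Sequence[np.ndarray],
    bins: int | np.ndarray = 50,
    pad_fraction: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Histogram each replica's series on shared edges.

    Default edges: ``bins`` equal bins over the pooled min-max range padded
    by ``pad_fraction`` on each side.  Returns (edges, per-replica relative
    frequencies, mean over replicas, SEM = sd/sqrt(n), ddof=1).
    """
    series = [np.asarray(s, dtype=float) for s in series]
    if isinstance(bins, (int, np.integer)):
        pooled = np.concatenate(series)
        lo, hi = float(pooled.min()), float(pooled.max())
        span = hi - lo
        if span == 0.0:
            span = max(abs(hi), 1.0)
        lo -= pad_fraction * span
        hi += pad_fraction * span
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    freqs = np.array([
        np.histogram(s, bins=edges)[0] / len(s) for s in series
    ])
    mean = freqs.mean(axis=0)
    n = freqs.shape[0]
    if n >= 2:
        sem = freqs.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return edges, freqs, mean, sem


def gate_series(
    trajectories: Sequence[Trajectory],
    pairs: Sequence[GatePairSpec],
    helices: tuple[HelixSpec, HelixSpec] | None = None,
    bins: int | np.ndarray = 50,
) -> GateGeometrySeries:
    """Distances I-IV and eta for several replicas, with histogram summary."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    distances: dict[str, list[np.ndarray]] = {p.label: [] for p in pairs}
    eta: list[np.ndarray] = []
    for traj in trajectories:
        for p in pairs:
            distances[p.label].append(pair_distance_series(traj, p))
        if helices is not None:
            eta.append(eta_series(traj, helices[0], helices[1]))
    histograms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    start_values: dict[str, float] = {}
    for label, series in distances.items():
        histograms[label] = replica_histogram(series, bins=bins)
        start_values[label] = float(series[0][0])
    if helices is not None:
        histograms["eta"] = replica_histogram(eta, bins=bins)
        start_values["eta"] = float(eta[0][0])
    return GateGeometrySeries(
        distances=distances, eta=eta, histograms=histograms,
        start_values=start_values,
        replica_ids=[t.replica_id for t in trajectories],
    )
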