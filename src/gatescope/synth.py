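"""Synthetic trajectory, helix, and lipid-field generators with known
ground truth.

The generators emulate the statistical regime of the microsecond
membrane-protein simulations the analyses are designed for: five
independent replicas, frames saved every 200 ps (5,000 frames per 1 us
replica at full scale), Gaussian fluctuation about a reference structure,
optional two-state hopping along a prescribed collective mode, and lipid
pseudo-particles at a 2:1 zwitterionic:anionic (PC:PG) composition.  All
output is bit-reproducible from (seed, parameters): each replica draws
from its own named substream spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AtomRecord, HelixSpec, Structure, Trajectory
from .gate import GatePairSpec, TurnSpec

__all__ = [
    "SynthSpec",
    "make_ideal_helix",
    "make_harmonic_trajectory",
    "make_two_state_trajectory",
    "make_gate_toy",
    "make_lipid_field",
    "make_translocon_toy",
]


@dataclass(frozen=True)
class SynthSpec:
    """Shared generator parameters.

    Defaults mirror the emulated production regime: 5 replicas, 200 ps
    between saved frames.  ``n_frames`` is per replica; tests use reduced
    counts, full scale is 5,000.
    """

    seed: int
    n_frames: int
    n_replicas: int = 5
    frame_spacing: float = 200.0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")

    def rngs(self) -> list[np.random.Generator]:
        """One independent generator per replica, spawned from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(self.n_replicas)
        return [np.random.default_rng(c) for c in children]


# Pseudo-backbone placement on the helical wheel: (radius A, phase offset
# deg, axial offset A) per atom, approximating ideal alpha-helix backbone
# cylinder radii.
_BACKBONE_OFFSETS = {
    "N": (1.5, -28.0, -0.85),
    "CA": (2.3, 0.0, 0.0),
    "C": (1.7, 21.0, 0.75),
    "O": (2.0, 27.0, 1.30),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto ``axis`` (unitized)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    vx = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * vx + (1 - np.cos(a)) * (vx @ vx)


def make_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    origin: np.ndarray = (0.0, 0.0, 0.0),
    chain_id: str = "A",
    first_residue: int = 1,
    label: str = "helix",
) -> Structure:
    """Ideal alpha-helix of backbone pseudo-atoms (N, CA, C, O).

    C-alpha atoms sit on a cylinder of the given radius, advancing by
    ``rise`` A and ``twist`` degrees per residue along ``axis``; the other
    backbone atoms are placed at canonical cylinder radii and wheel-phase
    offsets around each C-alpha.
    """
    if n_res < 8:
        raise ValueError("ideal helix fixture needs n_res >= 8")
    rot = _rotation_to(axis)
    origin = np.asarray(origin, dtype=float)
    atoms: list[AtomRecord] = []
    serial = 1
    scale = radius / 2.3  # keep relative backbone radii when radius varies
    for i in range(n_res):
        t0 = np.radians(i * twist)
        z0 = i * rise
        for name in ("N", "CA", "C", "O"):
            r, dphi, dz = _BACKBONE_OFFSETS[name]
            t = t0 + np.radians(dphi)
            local = np.array([scale * r * np.cos(t), scale * r * np.sin(t), z0 + dz])
            atoms.append(AtomRecord(
                serial=serial, name=name, element=_BACKBONE_ELEMENTS[name],
                residue_name="ALA", residue_id=first_residue + i,
                chain_id=chain_id, position=rot @ local + origin,
            ))
            serial += 1
    return Structure(atoms=atoms, label=label)


def rigid_body_basis(ref: Structure) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of infinitesimal rigid motions at ``ref``.

    Rows span the three uniform translations and the three rotations about
    the geometric center.  Collective modes used as generator ground truth
    are projected out of this subspace, since least-squares superposition
    removes exactly these degrees of freedom.
    """
    coords = ref.coords
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, (n, 3)), centered)
        basis.append(r.ravel())
    b = np.array(basis)
    # Gram-Schmidt (translations are already mutually orthogonal and
    # orthogonal to centered rotations)
    q: list[np.ndarray] = []
    for v in b:
        for u in q:
            v = v - (v @ u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            q.append(v / nv)
    return np.array(q)


def make_collective_mode(ref: Structure, seed: int) -> np.ndarray:
    """Random unit 3N mode orthogonal to all rigid-body motions of ``ref``.

    Such a mode is a genuine internal deformation: superposing frames onto
    a reference leaves displacements along it intact, so it serves as
    exact ground truth for PCA and two-state landscape recovery.
    """
    rng = np.random.default_rng(seed)
    n = len(ref)
    v = rng.normal(size=3 * n)
    for b in rigid_body_basis(ref):
        v = v - (v @ b) * b
    v = v / np.linalg.norm(v)
    return v.reshape(n, 3)


def make_harmonic_trajectory(
    ref: Structure,
    sigma: float | np.ndarray,
    spec: SynthSpec,
    rigid_motion: bool = False,
) -> list[Trajectory]:
    """Replicas of isotropic Gaussian fluctuation about ``ref``.

    ``sigma`` is the per-axis standard deviation (scalar or per atom), so
    the true all-atom RMSF is sigma * sqrt(3).  With ``rigid_motion`` a
    random proper rotation and translation is applied to every frame to
    exercise superposition.
    """
    n = len(ref)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    ref_coords = ref.coords
    out = []
    for rep, rng in enumerate(spec.rngs()):
        noise = rng.normal(0.0, 1.0, size=(spec.n_frames, n, 3)) * sigma[None, :, None]
        frames = ref_coords[None] + noise
        if rigid_motion:
            for f in range(spec.n_frames):
                rot = _random_rotation(rng)
                trans = rng.uniform(-20.0, 20.0, size=3)
                frames[f] = frames[f] @ rot.T + trans
        out.append(Trajectory(
            topology=ref, frames=frames,
            frame_spacing=spec.frame_spacing, replica_id=rep,
        ))
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_two_state_trajectory(
    ref: Structure,
    mode: np.ndarray,
    separation: float,
    p_major: float,
    noise_sigma: float,
    spec: SynthSpec,
) -> tuple[list[Trajectory], list[np.ndarray]]:
    """Two-basin hopping along a prescribed 3N collective mode.

    Each frame sits in basin A (the reference, probability ``p_major``) or
    basin B (reference + separation * mode) plus isotropic Gaussian noise.
    Returns the replicas and, as a side channel, the per-frame true basin
    labels (1 = minor basin B).
    """
    if not (0.5 <= p_major < 1.0) and p_major != 1.0:
        raise ValueError("p_major must be in [0.5, 1)")
    n = len(ref)
    mode = np.asarray(mode, dtype=float).reshape(n, 3)
    mode = mode / np.linalg.norm(mode)
    if separation <= 4.0 * noise_sigma:
        import warnings

        warnings.warn(
            "basin separation <= 4 * noise sigma: basins may merge",
            stacklevel=2,
        )
    ref_coords = ref.coords
    trajs: list[Trajectory] = []
    labels: list[np.ndarray] = []
    for rep, rng in enumerate(spec.rngs()):
        basin = (rng.random(spec.n_frames) >= p_major).astype(int)
        frames = (
            ref_coords[None]
            + basin[:, None, None] * separation * mode[None]
            + rng.normal(0.0, noise_sigma, size=(spec.n_frames, n, 3))
        )
        trajs.append(Trajectory(
            topology=ref, frames=frames,
            frame_spacing=spec.frame_spacing, replica_id=rep,
        ))
        labels.append(basin)
    return trajs, labels


def make_gate_toy(
    angle_schedule: np.ndarray,
    distance_schedule: np.ndarray,
    spec: SynthSpec,
    n_res: int = 12,
    noise_sigma: float = 0.0,
) -> tuple[Trajectory, dict, tuple[HelixSpec, HelixSpec], GatePairSpec]:
    """Two posed helices whose inter-axis angle and turn-COM distance
    follow prescribed per-frame schedules exactly.

    Both helices are copies of one template, so the axis estimated by
    ``helix_vector`` rotates rigidly with each pose and the programmed
    angle is recovered without construction bias.  Returns the trajectory,
    a ground-truth dict, the two HelixSpecs, and the distance GatePairSpec
    (the first four residues of each helix form the measured turns).
    """
    from .gate import helix_vector, turn_com  # local import to avoid cycle

    angle_schedule = np.asarray(angle_schedule, dtype=float)
    distance_schedule = np.asarray(distance_schedule, dtype=float)
    if angle_schedule.shape != distance_schedule.shape:
        raise ValueError("angle and distance schedules must have equal length")
    template = make_ideal_helix(n_res, chain_id="A", label="template")
    helix_a = HelixSpec("helixA", "A", 1, n_res)
    helix_b = HelixSpec("helixB", "B", 1, n_res)
    turn_a = TurnSpec("A", tuple(range(1, 5)), atom_class="all")
    turn_b = TurnSpec("B", tuple(range(1, 5)), atom_class="all")
    pair = GatePairSpec("I", turn_a, turn_b)

    # topology: chain A = template, chain B = renamed copy
    atoms = [a for a in template.atoms]
    nb = len(atoms)
    for a in template.atoms:
        atoms.append(AtomRecord(
            serial=a.serial + nb, name=a.name, element=a.element,
            residue_name=a.residue_name, residue_id=a.residue_id,
            chain_id="B", position=a.position.copy(),
        ))
    top = Structure(atoms=atoms, label="gate_toy")

    tcoords = template.coords
    v0 = helix_vector(tcoords, template, HelixSpec("t", "A", 1, n_res))
    c0 = turn_com(tcoords, template, TurnSpec("A", tuple(range(1, 5)), "all"))
    # rotation axis perpendicular to the measured template axis
    perp = np.cross(v0, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(v0, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    sep_dir = np.cross(v0, perp)
    sep_dir /= np.linalg.norm(sep_dir)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    frames = np.empty((len(angle_schedule), len(top), 3))
    for f, (theta, dist) in enumerate(zip(angle_schedule, distance_schedule)):
        rot = _rotation_about(perp, theta)
        coords_b = tcoords @ rot.T
        # place the measured turn COM of B at exactly `dist` from A's
        com_b = rot @ c0
        coords_b = coords_b + (c0 + dist * sep_dir - com_b)
        frame = np.vstack([tcoords, coords_b])
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        frames[f] = frame
    traj = Trajectory(topology=top, frames=frames, frame_spacing=spec.frame_spacing)
    truth = {"angle": angle_schedule.copy(), "distance": distance_schedule.copy()}
    return traj, truth, (helix_a, helix_b), pair


def make_lipid_field(
    n_particles: int,
    spec: SynthSpec,
    hotspot: tuple[np.ndarray, float, float] | None = None,
    class_ratio: tuple[int, int] = (2, 1),
    slab: tuple[np.ndarray, np.ndarray] = ((-40.0, -40.0, -20.0), (40.0, 40.0, 20.0)),
) -> list[Trajectory]:
    """Lipid head-group pseudo-particles over a slab, one replica per rng.

    Particles are re-drawn every frame: a ``hotspot = (center, sigma,
    fraction)`` sends that fraction of particles into an isotropic
    Gaussian blob (clipped to the slab is NOT applied; the analysis grid
    handles out-of-extent particles); the rest are uniform over the slab.
    Class labels split PC:PG by ``class_ratio`` (2:1 default, the emulated
    bilayer composition) and are fixed in the topology: residue names
    ``PC``/``PG``, one P atom per particle.
    """
    lo = np.asarray(slab[0], dtype=float)
    hi = np.asarray(slab[1], dtype=float)
    n_pc = int(round(n_particles * class_ratio[0] / sum(class_ratio)))
    atoms = []
    for i in range(n_particles):
        rname = "PC" if i < n_pc else "PG"
        atoms.append(AtomRecord(
            serial=i + 1, name="P", element="P", residue_name=rname,
            residue_id=i + 1, chain_id="L", position=np.zeros(3),
        ))
    top = Structure(atoms=atoms, label="lipid_field")
    if hotspot is not None:
        center, h_sigma, fraction = hotspot
        center = np.asarray(center, dtype=float)
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("hotspot fraction must be in [0, 1]")
    out: list[Trajectory] = []
    for rep, rng in enumerate(spec.rngs()):
        frames = rng.uniform(lo, hi, size=(spec.n_frames, n_particles, 3))
        if hotspot is not None and fraction > 0:
            in_spot = rng.random((spec.n_frames, n_particles)) < fraction
            blob = rng.normal(center, h_sigma, size=(spec.n_frames, n_particles, 3))
            frames = np.where(in_spot[:, :, None], blob, frames)
        out.append(Trajectory(
            topology=top, frames=frames,
            frame_spacing=spec.frame_spacing, replica_id=rep,
        ))
    return out


def make_translocon_toy(
    tmh7_tilt_deg: float = 5.0,
    tmh2b_shift: float = 5.0,
    hairpin_tilt_deg: float = 30.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Synthetic stand-in for a translocon-like two-state helix bundle.

    This is NOT a deposited structure: it is an idealized construct (the
    filename-free, purely generated analogue) used to exercise the
    deposited-structure geometry machinery — bundle-normal estimation,
    hairpin tilt, inter-state helix tilt via a chain map, and per-residue
    C-alpha displacement.  Ten pore-forming helices (chain Y) stand
    roughly along z on a 14 A circle; an accessory two-helix hairpin
    (chain E) is tilted by ``hairpin_tilt_deg`` from the bundle normal.
    In the "bound" state helix 7 is tilted by an extra ``tmh7_tilt_deg``
    about its midpoint and helix 2b is rigidly shifted ``tmh2b_shift`` A
    toward the pore axis; the "relaxed" state (chain ids lower-cased, to
    exercise the chain map) has neither change.

    Returns a dict with both Structures, the HelixSpecs, and the chain map
    relaxed-state lookup.
    """
    rng = np.random.default_rng(seed)
    n_res = 22  # terminal-turn phases realign at 22 residues (100 deg twist)
    helices_y: list[HelixSpec] = []
    pieces_bound: list[Structure] = []
    pieces_relaxed: list[Structure] = []
    # ring kept narrow relative to helix length so the bundle's first
    # principal axis is unambiguously the membrane normal
    ring_radius = 8.0

    def helix_atoms(k: int, axis, origin, chain: str, first_res: int):
        return make_ideal_helix(
            n_res, axis=axis, origin=origin, chain_id=chain,
            first_residue=first_res, label=f"TMH{k}",
        )

    # ten bundle helices, alternating direction; each is spun about its own
    # axis by the ring angle so helical-wheel offsets cancel across the
    # bundle and the pooled principal axis is clean
    for k in range(10):
        ang = 2 * np.pi * k / 10
        origin = np.array([ring_radius * np.cos(ang), ring_radius * np.sin(ang), -16.0])
        axis = np.array([0.0, 0.0, 1.0 if k % 2 == 0 else -1.0])
        if axis[2] < 0:
            origin = origin + np.array([0.0, 0.0, 32.0])
        first_res = 50 * k + 1
        h = helix_atoms(k + 1, axis, origin, "Y", first_res)
        spin = _rotation_about(axis, np.degrees(ang))
        hc = h.coords
        center = hc.mean(axis=0)
        h = h.with_coords((hc - center) @ spin.T + center)
        helices_y.append(HelixSpec(f"TMH{k + 1}", "Y", first_res, first_res + n_res - 1))
        pieces_bound.append(h)
        pieces_relaxed.append(h)

    # bound-state modifications: helix 7 (index 6) tilted, helix 2b
    # (index 2) shifted toward the pore axis
    def retilt(s: Structure, angle: float) -> Structure:
        coords = s.coords
        center = coords.mean(axis=0)
        rot = _rotation_about(np.array([0.0, 1.0, 0.0]), angle)
        return s.with_coords((coords - center) @ rot.T + center)

    def shift_inward(s: Structure, dist: float) -> Structure:
        coords = s.coords
        center = coords.mean(axis=0)
        inward = -np.array([center[0], center[1], 0.0])
        inward /= np.linalg.norm(inward)
        return s.with_coords(coords + dist * inward)

    pieces_bound[6] = retilt(pieces_bound[6], tmh7_tilt_deg)
    pieces_bound[2] = shift_inward(pieces_bound[2], tmh2b_shift)

    # accessory hairpin (chain E): two antiparallel helices, shared axis
    # tilted by hairpin_tilt_deg from z, placed outside the ring
    tilt_rot = _rotation_about(np.array([0.0, 1.0, 0.0]), hairpin_tilt_deg)
    up = tilt_rot @ np.array([0.0, 0.0, 1.0])
    base = np.array([ring_radius + 12.0, 0.0, -14.0])
    e1 = make_ideal_helix(n_res, axis=up, origin=base, chain_id="E",
                          first_residue=1, label="E-TMH1")
    e2 = make_ideal_helix(n_res, axis=-up, origin=base + up * (n_res * 1.5)
                          + np.array([6.0, 0.0, 0.0]),
                          chain_id="E", first_residue=101, label="E-TMH2")
    hairpin = (HelixSpec("E-TMH1", "E", 1, n_res),
               HelixSpec("E-TMH2", "E", 101, 100 + n_res))
    pieces_bound += [e1, e2]
    pieces_relaxed += [e1, e2]

    def assemble(pieces: list[Structure], lowercase: bool, label: str) -> Structure:
        atoms: list[AtomRecord] = []
        serial = 1
        for p in pieces:
            for a in p.atoms:
                chain = a.chain_id.lower() if lowercase else a.chain_id
                pos = a.position + (
                    rng.normal(0.0, noise_sigma, 3) if noise_sigma > 0 else 0.0
                )
                atoms.append(AtomRecord(
                    serial=serial, name=a.name, element=a.element,
                    residue_name=a.residue_name, residue_id=a.residue_id,
                    chain_id=chain, position=pos,
                ))
                serial += 1
        return Structure(atoms=atoms, label=label)

    bound = assemble(pieces_bound, lowercase=False, label="synthetic-bound")
    relaxed = assemble(pieces_relaxed, lowercase=True, label="synthetic-relaxed")
    return {
        "bound": bound,
        "relaxed": relaxed,
        "helices": helices_y,
        "hairpin": hairpin,
        "chain_map": {"Y": "y", "E": "e"},
        "tmh2b": helices_y[2],
        "tmh7": helices_y[6],
    }
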