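"""Shared fixtures: tiny hand-built structures and generated trajectories."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import gatescope as gs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def build_structure(spec: list[tuple[str, int, str, str, tuple]], label="toy"):
    """Build a Structure from (chain, resid, resname, atom name, xyz) rows."""
    atoms = [
        gs.AtomRecord(
            serial=i + 1, name=name, element="", residue_name=rname,
            residue_id=rid, chain_id=chain, position=np.asarray(pos, float),
        )
        for i, (chain, rid, rname, name, pos) in enumerate(spec)
    ]
    return gs.Structure(atoms=atoms, label=label)


@pytest.fixture
def two_chain_structure():
    """Chain Y: two residues with backbone + CB; chain E: one residue with H."""
    rows = []
    for rid in (10, 11):
        for j, name in enumerate(("N", "CA", "C", "O", "CB")):
            rows.append(("Y", rid, "ALA", name, (rid + 0.1 * j, float(j), 0.0)))
    for j, name in enumerate(("N", "CA", "C", "O", "HA")):
        rows.append(("E", 5, "GLY", name, (50.0 + j, 0.0, 1.0)))
    return build_structure(rows)


@pytest.fixture
def small_helix():
    return gs.make_ideal_helix(12)


@pytest.fixture
def helix20():
    return gs.make_ideal_helix(20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
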