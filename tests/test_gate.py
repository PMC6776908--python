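"""Gate geometry: turn COMs, distances, helix axes, eta, tilt, histograms."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gatescope as gs

from conftest import build_structure, random_rotation


def square_turn(masses_all_carbon=True):
    """Four unit-square atoms in z=0, one residue each? No — one turn needs
    4 consecutive residues; place one atom per residue at the corners."""
    rows = [
        ("A", 1, "GLY", "CA", (0.0, 0.0, 0.0)),
        ("A", 2, "GLY", "CA", (1.0, 0.0, 0.0)),
        ("A", 3, "GLY", "CA", (1.0, 1.0, 0.0)),
        ("A", 4, "GLY", "CA", (0.0, 1.0, 0.0)),
    ]
    return build_structure(rows)


class TestTurnCom:
    def test_unit_square_center(self):
        s = square_turn()
        spec = gs.TurnSpec("A", (1, 2, 3, 4), "all")
        com = gs.turn_com(s.coords, s, spec)
        assert np.allclose(com, [0.5, 0.5, 0.0])

    def test_mass_weighting(self):
        # C (12.011) at x=0 and O (15.999) at x=7 within one turn
        rows = [
            ("A", 1, "GLY", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "GLY", "O", (7.0, 0.0, 0.0)),
            ("A", 3, "GLY", "C", (0.0, 0.0, 0.0)),
            ("A", 4, "GLY", "O", (7.0, 0.0, 0.0)),
        ]
        s = build_structure(rows)
        com = gs.turn_com(s.coords, s, gs.TurnSpec("A", (1, 2, 3, 4), "all"))
        expected = 2 * 15.999 * 7.0 / (2 * 12.011 + 2 * 15.999)
        assert com[0] == pytest.approx(expected, rel=1e-9)
        # the hand value for masses 12 and 16 exactly: 16*7/28 = 4.0
        assert com[0] == pytest.approx(4.0, abs=0.01)

    def test_translation_equivariance(self):
        s = square_turn()
        spec = gs.TurnSpec("A", (1, 2, 3, 4), "all")
        t = np.array([3.0, -2.0, 9.0])
        com0 = gs.turn_com(s.coords, s, spec)
        com1 = gs.turn_com(s.coords + t, s, spec)
        assert np.allclose(com1 - com0, t, atol=1e-12)

    def test_missing_residue_named(self):
        s = square_turn()
        with pytest.raises(gs.SpecResolutionError, match="5"):
            gs.turn_com(s.coords, s, gs.TurnSpec("A", (2, 3, 4, 5), "all"))

    def test_nonconsecutive_residues_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            gs.TurnSpec("A", (1, 2, 4, 5), "all")


class TestPairDistance:
    def _toy(self):
        rows = [("A", i, "GLY", "CA", (0.0, 0.0, float(i))) for i in range(1, 5)]
        rows += [("B", i, "GLY", "CA", (3.0, 4.0, float(i))) for i in range(1, 5)]
        return build_structure(rows)

    def test_three_four_five(self):
        s = self._toy()
        pair = gs.GatePairSpec(
            "I", gs.TurnSpec("A", (1, 2, 3, 4)), gs.TurnSpec("B", (1, 2, 3, 4))
        )
        traj = gs.Trajectory(topology=s, frames=s.coords[None])
        assert gs.pair_distance_series(traj, pair)[0] == pytest.approx(5.0)

    def test_identical_turns_zero(self):
        rows = [("A", i, "GLY", "CA", (1.0, 2.0, 3.0 + 0 * i)) for i in range(1, 5)]
        rows += [("B", i, "GLY", "CA", (1.0, 2.0, 3.0)) for i in range(1, 5)]
        # distinct positions needed per atom key; same COM either way
        s = build_structure(rows)
        pair = gs.GatePairSpec(
            "I", gs.TurnSpec("A", (1, 2, 3, 4)), gs.TurnSpec("B", (1, 2, 3, 4))
        )
        traj = gs.Trajectory(topology=s, frames=np.stack([s.coords] * 3))
        assert np.allclose(gs.pair_distance_series(traj, pair), 0.0)

    def test_rigid_rotation_invariance(self, rng):
        s = self._toy()
        pair = gs.GatePairSpec(
            "I", gs.TurnSpec("A", (1, 2, 3, 4)), gs.TurnSpec("B", (1, 2, 3, 4))
        )
        frames = np.stack([s.coords] * 5)
        for f in range(5):
            frames[f] = frames[f] @ random_rotation(rng).T + rng.uniform(-9, 9, 3)
        traj = gs.Trajectory(topology=s, frames=frames)
        assert np.allclose(gs.pair_distance_series(traj, pair), 5.0, atol=1e-9)


class TestHelixVector:
    def test_axis_recovery_within_one_degree(self, helix20):
        v = gs.helix_vector(
            helix20.coords, helix20, gs.HelixSpec("h", "A", 1, 20)
        )
        dev = np.degrees(np.arccos(np.clip(abs(v[2]), 0, 1)))
        assert dev < 1.0

    def test_orientation_follows_residue_order(self, helix20):
        v = gs.helix_vector(helix20.coords, helix20, gs.HelixSpec("h", "A", 1, 20))
        assert v[2] > 0  # built along +z, N -> C upward

    def test_rotation_equivariance(self, helix20, rng):
        spec = gs.HelixSpec("h", "A", 1, 20)
        v0 = gs.helix_vector(helix20.coords, helix20, spec)
        rot = random_rotation(rng)
        v1 = gs.helix_vector(helix20.coords @ rot.T, helix20, spec)
        assert np.allclose(v1, rot @ v0, atol=1e-12)


class TestEta:
    def _pair_at(self, theta_deg):
        spec = gs.SynthSpec(seed=1, n_frames=1)
        traj, _, helices, _ = gs.make_gate_toy(
            np.array([theta_deg]), np.array([10.0]), spec
        )
        return traj, helices

    @pytest.mark.parametrize("theta", [0.0, 30.0, 180.0])
    def test_programmed_angles(self, theta):
        traj, (h7, h8) = self._pair_at(theta)
        eta = gs.eta_angle(traj.frames[0], traj.topology, h7, h8)
        assert eta == pytest.approx(theta, abs=1.0)

    def test_cos_constructed_angle(self):
        theta = float(np.degrees(np.arccos(0.8660)))
        traj, (h7, h8) = self._pair_at(theta)
        eta = gs.eta_angle(traj.frames[0], traj.topology, h7, h8)
        assert eta == pytest.approx(30.0, abs=1.0)

    def test_symmetry_in_arguments(self):
        traj, (h7, h8) = self._pair_at(42.0)
        f = traj.frames[0]
        assert gs.eta_angle(f, traj.topology, h7, h8) == pytest.approx(
            gs.eta_angle(f, traj.topology, h8, h7), abs=1e-12
        )


class TestHelixTilt:
    def test_single_helix_along_normal(self):
        h = gs.make_ideal_helix(22)
        assert gs.helix_tilt(h, gs.HelixSpec("h", "A", 1, 22), [0, 0, 1]) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_helix_perpendicular_to_normal(self):
        h = gs.make_ideal_helix(22, axis=(1.0, 0.0, 0.0))
        assert gs.helix_tilt(h, gs.HelixSpec("h", "A", 1, 22), [0, 0, 1]) == (
            pytest.approx(90.0, abs=1e-9)
        )

    def test_parallel_pair_as_hairpin_rejected(self):
        h1 = gs.make_ideal_helix(22, chain_id="A")
        h2 = gs.make_ideal_helix(22, chain_id="B", origin=(8.0, 0.0, 0.0))
        atoms = h1.atoms + [
            dataclasses.replace(a, serial=a.serial + 100) for a in h2.atoms
        ]
        s = gs.Structure(atoms=atoms)
        with pytest.raises(gs.SpecResolutionError, match="degenerate"):
            gs.helix_tilt(
                s,
                (gs.HelixSpec("a", "A", 1, 22), gs.HelixSpec("b", "B", 1, 22)),
                [0, 0, 1],
            )

    def test_synthetic_hairpin_tilt_recovered(self):
        toy = gs.make_translocon_toy(hairpin_tilt_deg=30.0)
        normal = gs.membrane_normal(toy["bound"], "chain Y")
        tilt = gs.helix_tilt(toy["bound"], toy["hairpin"], normal)
        assert tilt == pytest.approx(30.0, abs=1.5)

    def test_interstate_tilt_matches_programmed(self):
        toy = gs.make_translocon_toy(tmh7_tilt_deg=5.0)
        fit = "chain Y and (" + " or ".join(
            f"resid {h.first_residue}-{h.last_residue}"
            for i, h in enumerate(toy["helices"]) if i in (5, 7, 8, 9)
        ) + ")"
        tilt = gs.interstate_helix_tilt(
            toy["bound"], toy["relaxed"], toy["tmh7"], fit, toy["chain_map"]
        )
        assert tilt == pytest.approx(5.0, abs=0.5)


class TestGateSeries:
    def test_identical_single_frame_replicas(self):
        spec = gs.SynthSpec(seed=2, n_frames=1)
        traj, _, helices, pair = gs.make_gate_toy(
            np.array([25.0]), np.array([11.0]), spec
        )
        trajs = [
            gs.Trajectory(topology=traj.topology, frames=traj.frames,
                          replica_id=r)
            for r in range(5)
        ]
        series = gs.gate_series(trajs, [pair], helices)
        for label in ("I", "eta"):
            _, freqs, mean, sem = series.histograms[label]
            assert (mean > 0).sum() == 1
            assert np.allclose(sem, 0.0)
            assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_step_schedule_detected(self):
        n = 40
        angles = np.where(np.arange(n) < n // 2, 10.0, 40.0)
        dists = np.full(n, 12.0)
        traj, truth, helices, pair = gs.make_gate_toy(
            angles, dists, gs.SynthSpec(seed=3, n_frames=n)
        )
        eta = gs.eta_series(traj, *helices)
        assert np.allclose(eta[: n // 2], 10.0, atol=1.0)
        assert np.allclose(eta[n // 2:], 40.0, atol=1.0)
        # distance schedule honored independently
        d = gs.pair_distance_series(traj, pair)
        assert np.allclose(d, 12.0, atol=0.1)

    def test_sem_matches_replica_scatter(self):
        # distances ~ N(d0, sigma^2): per-bin SEM == sd/sqrt(5) by definition
        rng = np.random.default_rng(8)
        series = [rng.normal(10.0, 1.0, 400) for _ in range(5)]
        edges, freqs, mean, sem = gs.replica_histogram(series, bins=20)
        manual = freqs.std(axis=0, ddof=1) / np.sqrt(5)
        assert np.allclose(sem, manual)
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_start_value_reported(self):
        spec = gs.SynthSpec(seed=4, n_frames=3)
        traj, _, helices, pair = gs.make_gate_toy(
            np.array([20.0, 25.0, 30.0]), np.array([9.0, 10.0, 11.0]), spec
        )
        series = gs.gate_series([traj], [pair], helices)
        assert series.start_values["I"] == pytest.approx(9.0, abs=0.1)
        assert series.start_values["eta"] == pytest.approx(20.0, abs=1.0)


class TestAngleGridRecovery:
    @pytest.mark.parametrize("theta", [0.0, 15.0, 30.0, 60.0, 90.0])
    def test_programmed_axis_angles(self, theta):
        traj, truth, helices, pair = gs.make_gate_toy(
            np.full(3, theta), np.full(3, 10.0),
            gs.SynthSpec(seed=5, n_frames=3),
        )
        eta = gs.eta_series(traj, *helices)
        assert np.abs(eta - theta).max() < 1.5
        d = gs.pair_distance_series(traj, pair)
        assert np.abs(d - 10.0).max() < 0.1
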