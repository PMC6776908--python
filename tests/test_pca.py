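"""PCA, free-energy landscapes, representative conformations, porcupines."""

from __future__ import annotations

import numpy as np
import pytest

import gatescope as gs
from gatescope.pca import R_KCAL

from conftest import build_structure


def jacobi_eigenvalues(a: np.ndarray, sweeps: int = 100) -> np.ndarray:
    """Independent brute-force Jacobi eigensolver for small symmetric
    matrices (cyclic sweeps of 2x2 rotations)."""
    a = a.copy().astype(float)
    n = a.shape[0]
    for _ in range(sweeps):
        off = np.sqrt(sum(a[i, j] ** 2 for i in range(n) for j in range(n) if i != j))
        if off < 1e-14:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < 1e-16:
                    continue
                theta = 0.5 * np.arctan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = np.cos(theta), np.sin(theta)
                rot = np.eye(n)
                rot[p, p] = c
                rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
    return np.sort(np.diag(a))[::-1]


def single_mode_traj(n_frames=400, amp_sigma=1.5, seed=5):
    """Trajectory whose only motion is one internal collective mode."""
    ref = gs.make_ideal_helix(10)
    mode = gs.make_collective_mode(ref, seed)
    rng = np.random.default_rng(seed)
    c = rng.normal(0, amp_sigma, n_frames)
    frames = ref.coords[None] + c[:, None, None] * mode[None]
    return gs.Trajectory(topology=ref, frames=frames), mode, c


class TestFitPca:
    def test_single_mode_dominates(self):
        traj, mode, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        assert model.explained_fraction[0] > 0.999
        assert abs(model.eigenvectors[0] @ mode.ravel()) > 0.999

    def test_two_mode_explained_fractions(self):
        ref = gs.make_ideal_helix(20)
        u1 = gs.make_collective_mode(ref, 11)
        u2 = gs.make_collective_mode(ref, 12)
        u2 = u2 - (u2.ravel() @ u1.ravel()) * u1
        u2 /= np.linalg.norm(u2)
        rng = np.random.default_rng(31)
        c1 = rng.normal(0, 2.0, 3000)
        c2 = rng.normal(0, 1.0, 3000)
        frames = (
            ref.coords[None]
            + c1[:, None, None] * u1[None]
            + c2[:, None, None] * u2[None]
        )
        model = gs.fit_pca(
            [gs.Trajectory(topology=ref, frames=frames)], "all", "all"
        )
        ef = model.explained_fraction
        assert ef[0] == pytest.approx(0.8, abs=0.03)
        assert ef[1] == pytest.approx(0.2, abs=0.03)
        assert abs(model.eigenvectors[0] @ u1.ravel()) > 0.99

    def test_orthonormal_and_sorted(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "calpha")
        g = model.eigenvectors @ model.eigenvectors.T
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_trace_conservation(self):
        traj, _, _ = single_mode_traj(n_frames=300)
        model = gs.fit_pca([traj], "all", "all")
        fitted = gs.superpose_frames(
            traj.frames, model.reference_coords, model.fit_indices
        )
        data = fitted[:, model.analysis_indices, :].reshape(traj.n_frames, -1)
        total_var = data.var(axis=0, ddof=0).sum()
        assert model.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_jacobi_oracle_agreement(self):
        # covariance of a 4-atom (12-dim) toy against an independent solver
        rng = np.random.default_rng(41)
        data = rng.normal(size=(500, 12)) @ np.diag(np.linspace(0.2, 2.0, 12))
        cov = np.cov(data.T, ddof=0)
        lam_jacobi = jacobi_eigenvalues(cov)
        lam_np = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(lam_jacobi, lam_np, atol=1e-8)

    def test_insufficient_frames(self):
        ref = gs.make_ideal_helix(8)
        traj = gs.Trajectory(topology=ref, frames=ref.coords[None])
        with pytest.raises(ValueError, match="2 pooled frames"):
            gs.fit_pca([traj], "all", "all")


class TestProject:
    def test_mean_projects_to_origin(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        mean_frame = model.reference_coords.copy()
        mean_frame[model.analysis_indices] = model.mean_coords.reshape(-1, 3)
        proj = gs.project_frames(mean_frame[None], model, k=2)[0]
        assert np.allclose(proj, 0.0, atol=1e-8)

    def test_mean_plus_pc1_projects_to_c(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        c = 2.5
        frame = model.reference_coords.copy()
        frame[model.analysis_indices] = (
            model.mean_coords + c * model.eigenvectors[0]
        ).reshape(-1, 3)
        proj = gs.project_frames(frame[None], model, k=2)[0]
        assert proj[0] == pytest.approx(c, abs=1e-6)
        assert proj[1] == pytest.approx(0.0, abs=1e-6)

    def test_full_reconstruction(self):
        traj, _, _ = single_mode_traj(n_frames=50)
        model = gs.fit_pca([traj], "all", "all")
        k = model.eigenvectors.shape[0]
        fitted = gs.superpose_frames(
            traj.frames, model.reference_coords, model.fit_indices
        )
        data = fitted[:, model.analysis_indices, :].reshape(50, -1)
        proj = (data - model.mean_coords) @ model.eigenvectors[:k].T
        recon = model.mean_coords + proj @ model.eigenvectors[:k]
        assert np.allclose(recon, data, atol=1e-8)

    def test_k_out_of_range(self):
        traj, _, _ = single_mode_traj(n_frames=20)
        model = gs.fit_pca([traj], "all", "all")
        with pytest.raises(ValueError, match="exceeds"):
            gs.project(traj, model, k=10_000)


class TestLandscape:
    def test_single_bin_all_frames(self):
        pts = np.zeros((50, 2))
        fel = gs.landscape(pts, bins=5)
        occ = fel.counts > 0
        assert occ.sum() == 1
        assert fel.delta_g[occ][0] == 0.0
        assert np.all(np.isinf(fel.delta_g[~occ]))

    def test_half_max_closed_form(self):
        pts = np.concatenate([
            np.tile([[-1.0, 0.0]], (100, 1)), np.tile([[1.0, 0.0]], (50, 1))
        ])
        fel = gs.landscape(pts, bins=2, temperature=300.0)
        vals = np.sort(fel.delta_g[fel.counts > 0])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(R_KCAL * 300.0 * np.log(2), abs=1e-6)
        assert vals[1] == pytest.approx(0.4132, abs=5e-4)

    def test_80_20_occupancy_difference(self):
        pts = np.concatenate([
            np.tile([[-1.0, 0.0]], (800, 1)), np.tile([[1.0, 0.0]], (200, 1))
        ])
        fel = gs.landscape(pts, bins=2)
        vals = np.sort(fel.delta_g[fel.counts > 0])
        assert vals[1] - vals[0] == pytest.approx(-R_KCAL * 300 * np.log(0.25),
                                                  abs=1e-6)
        assert vals[1] == pytest.approx(0.8265, abs=5e-4)

    def test_counts_sum_to_frames(self, rng):
        pts = rng.normal(size=(777, 2))
        fel = gs.landscape(pts, bins=20)
        assert fel.counts.sum() == 777

    def test_uniform_count_addition_compresses_differences(self, rng):
        pts = rng.normal(size=(500, 2))
        fel = gs.landscape(pts, bins=8)
        occ = fel.counts > 0
        boosted = fel.counts.copy()
        boosted[occ] += 50
        dg2 = -R_KCAL * 300 * np.log(boosted[occ] / boosted.max())
        spread_before = np.ptp(fel.delta_g[occ])
        spread_after = np.ptp(dg2)
        assert spread_after < spread_before


class TestLocateAndRepresentative:
    def _two_state(self, n_frames=1500, p=0.8, seed=23):
        ref = gs.make_ideal_helix(12)
        mode = gs.make_collective_mode(ref, seed)
        trajs, labels = gs.make_two_state_trajectory(
            ref, mode, 6.0, p, 0.4,
            gs.SynthSpec(seed=seed, n_frames=n_frames, n_replicas=1),
        )
        return ref, mode, trajs, labels

    def test_minimum_frame_locates_to_zero(self):
        ref, mode, trajs, _ = self._two_state()
        model = gs.fit_pca(trajs, "all", "all")
        proj = gs.project(trajs[0], model)
        fel = gs.landscape(proj, bins=20)
        imax = np.unravel_index(np.argmax(fel.counts), fel.counts.shape)
        # any frame inside the max bin has dG exactly 0
        for f in range(trajs[0].n_frames):
            ix, iy, _ = fel.bin_of(proj[f])
            if (ix, iy) == tuple(imax):
                dg, inside = gs.locate_conformation(
                    trajs[0].frame_structure(f), model, fel
                )
                assert inside and dg == 0.0
                break
        else:
            pytest.fail("no frame found in the maximum bin")

    def test_minor_basin_reference_energy(self):
        ref, mode, trajs, _ = self._two_state(n_frames=4000, p=0.8)
        model = gs.fit_pca(trajs, "all", "all")
        proj = gs.project(trajs[0], model)
        fel = gs.landscape(proj, bins=12)
        minor_ref = ref.with_coords(ref.coords + 6.0 * mode)
        dg, inside = gs.locate_conformation(minor_ref, model, fel)
        assert inside
        assert dg == pytest.approx(-R_KCAL * 300 * np.log(0.25), abs=0.35)

    def test_out_of_range_flagged(self):
        ref, mode, trajs, _ = self._two_state(n_frames=200)
        model = gs.fit_pca(trajs, "all", "all")
        fel = gs.landscape(gs.project(trajs[0], model), bins=10)
        far = ref.with_coords(ref.coords + 500.0 * mode)
        dg, inside = gs.locate_conformation(far, model, fel)
        assert not inside
        assert np.isfinite(dg) or np.isinf(dg)  # nearest-bin value reported

    def test_representative_in_major_basin_and_deterministic(self):
        ref, mode, trajs, labels = self._two_state(n_frames=1000, p=0.8)
        model = gs.fit_pca(trajs, "all", "all")
        fel = gs.landscape(gs.project(trajs[0], model), bins=15)
        rep1 = gs.representative_conformation(trajs, model, fel)
        rep2 = gs.representative_conformation(trajs, model, fel)
        assert rep1 == rep2
        r, f = rep1
        assert labels[r][f] == 0  # major basin

    def test_single_frame_trajectory(self):
        ref = gs.make_ideal_helix(10)
        mode = gs.make_collective_mode(ref, 3)
        frames = np.stack([ref.coords, ref.coords + 0.2 * mode])
        traj = gs.Trajectory(topology=ref, frames=frames)
        model = gs.fit_pca([traj], "all", "all")
        one = gs.Trajectory(topology=ref, frames=ref.coords[None])
        fel = gs.landscape(gs.project(one, model), bins=3)
        assert gs.representative_conformation([one], model, fel) == (0, 0)


class TestPorcupine:
    def test_cutoff_zero_keeps_all_atoms(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        idx, arrows = gs.pc_displacement_vectors(model, 0, cutoff=0.0)
        assert len(idx) == len(model.analysis_indices)

    def test_cutoff_above_max_empties(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        idx, arrows = gs.pc_displacement_vectors(model, 0, cutoff=1e9)
        assert len(idx) == 0

    def test_arrows_parallel_to_programmed_mode(self):
        traj, mode, c = single_mode_traj(n_frames=600, amp_sigma=2.0)
        model = gs.fit_pca([traj], "all", "all")
        idx, arrows = gs.pc_displacement_vectors(model, 0, cutoff=0.0)
        # stack arrows back into a 3N vector and compare direction
        v = np.zeros((len(traj.topology), 3))
        v[idx] = arrows
        cosang = abs(
            v.ravel() @ mode.ravel() / np.linalg.norm(v.ravel())
        )
        assert cosang > 0.99

    def test_amplitude_scaling(self):
        traj, _, _ = single_mode_traj()
        model = gs.fit_pca([traj], "all", "all")
        _, a1 = gs.pc_displacement_vectors(model, 0, scale=1.0)
        _, a2 = gs.pc_displacement_vectors(model, 0, scale=2.0)
        assert np.allclose(a2, 2 * a1)
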