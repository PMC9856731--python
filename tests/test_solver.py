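"""Scalar-potential solver: oracle cases, conservation, convergence."""

import numpy as np
import pytest

from tmsmap.coil import CoilModel
from tmsmap.head import HeadGeometry, VoxelHeadModel, build_synthetic_head
from tmsmap.solver import (
    SolverConvergenceError,
    assemble_system,
    reconstruct_ef,
    solve_placement,
    solve_potential,
)

FULL_TABLE = {1: 0.465, 2: 0.010, 3: 1.654, 4: 0.275, 5: 0.126}


def cube_head(n=32, sigma=0.3, h=1.0):
    labels = np.zeros((n, n, n), np.int16)
    labels[1:-1, 1:-1, 1:-1] = 4
    affine = np.diag([h, h, h, 1.0])
    return VoxelHeadModel(labels, h, affine, {4: sigma})


def sphere_head(radius_mm=20.0, h=1.0, layers=None):
    """Conducting ball (optionally 3 concentric layers) in an air box."""
    n = int(2 * radius_mm / h) + 6
    c = (np.arange(n) + 0.5) * h - n * h / 2.0
    gx, gy, gz = np.meshgrid(c, c, c, indexing="ij")
    r = np.sqrt(gx**2 + gy**2 + gz**2)
    labels = np.zeros((n, n, n), np.int16)
    if layers is None:
        labels[r < radius_mm] = 4
        table = {4: 0.275}
    else:
        for lab, rad in layers:
            labels[r < rad] = lab
        table = {lab: FULL_TABLE[lab] for lab, _ in layers}
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = -n * h / 2.0
    return VoxelHeadModel(labels, h, affine, table)


def loop_dadt(head, loop_z_mm=30.0, radius_mm=25.0, didt=100.0):
    """dA/dt of a single circular loop above the model (dipole-like source)."""
    from tmsmap.coil import biot_savart_dAdt

    th = np.linspace(0, 2 * np.pi, 73)
    pts = np.stack(
        [radius_mm * np.cos(th), radius_mm * np.sin(th), np.full_like(th, loop_z_mm)],
        1,
    )
    mid, dl = 0.5 * (pts[:-1] + pts[1:]), pts[1:] - pts[:-1]
    centers = head.voxel_centers_world().reshape(-1, 3)
    a = biot_savart_dAdt(mid, dl, centers, didt)
    return a.reshape(head.labels.shape + (3,))


class TestAssembly:
    def test_uniform_source_rhs_vanishes_in_interior(self):
        head = cube_head(16)
        dadt = np.zeros(head.labels.shape + (3,))
        dadt[..., 0] = 2.5
        system = assemble_system(head, dadt)
        assert abs(system.b.sum()) < 1e-10 * np.abs(system.b).max()
        # nonzero entries only at the conductor boundary
        interior = np.zeros(head.labels.shape, bool)
        interior[2:-2, 2:-2, 2:-2] = True
        b_grid = np.zeros(head.labels.shape)
        b_grid[system.index >= 0] = system.b
        assert np.all(b_grid[interior] == 0)

    def test_row_sums_vanish_pure_neumann(self):
        head = cube_head(10)
        system = assemble_system(head, np.zeros(head.labels.shape + (3,)))
        assert np.abs(np.asarray(system.matrix.sum(axis=1))).max() < 1e-12

    def test_no_conductor_raises(self):
        head = cube_head(8)
        head.labels[:] = 0
        with pytest.raises(ValueError, match="no conducting"):
            assemble_system(head, np.zeros(head.labels.shape + (3,)))


class TestSolve:
    def test_uniform_field_in_homogeneous_conductor_cancels(self):
        """Uniform dA/dt: surface charge makes the interior field vanish."""
        head = cube_head(32)
        dadt = np.zeros(head.labels.shape + (3,))
        dadt[..., 0] = 1.0
        system = assemble_system(head, dadt)
        sol = solve_potential(system, tol=1e-8)
        ef = reconstruct_ef(sol, dadt, head)
        assert np.abs(ef.E).max() < 1e-3

    def test_iterative_matches_dense_solve(self):
        """Brute-force oracle: dense minimum-norm solve on a tiny system."""
        rng = np.random.default_rng(0)
        n = 12
        labels = np.zeros((n, n, n), np.int16)
        labels[1:-1, 1:-1, 1:-1] = rng.integers(1, 6, (n - 2,) * 3).astype(np.int16)
        head = VoxelHeadModel(labels, 1.0, np.diag([1.0, 1, 1, 1]), FULL_TABLE)
        dadt = rng.normal(size=(n, n, n, 3))
        system = assemble_system(head, dadt)
        dense = np.linalg.lstsq(system.matrix.toarray(), system.b, rcond=None)[0]
        dense -= dense.mean()
        sol = solve_potential(system, tol=1e-13, max_iter=20000)
        phi = sol.phi[system.index >= 0]
        scale = np.abs(dense).max()
        assert np.abs(phi - dense).max() < 1e-8 * max(scale, 1.0)

    def test_linearity_in_rhs(self):
        head = cube_head(12)
        dadt = loop_dadt(head)
        system = assemble_system(head, dadt)
        sol1 = solve_potential(system, tol=1e-10)
        system.b *= 2.0
        sol2 = solve_potential(system, tol=1e-10)
        phi1 = sol1.phi[sol1.conducting]
        phi2 = sol2.phi[sol2.conducting]
        assert np.allclose(phi2, 2.0 * phi1, rtol=1e-6, atol=1e-12)

    def test_zero_mean_gauge(self):
        head = cube_head(12)
        dadt = loop_dadt(head)
        sol = solve_potential(assemble_system(head, dadt), tol=1e-8)
        assert abs(sol.phi[sol.conducting].mean()) < 1e-12

    def test_nonconvergence_carries_history(self):
        head = cube_head(16)
        dadt = loop_dadt(head)
        with pytest.raises(SolverConvergenceError) as exc:
            solve_potential(assemble_system(head, dadt), tol=1e-12, max_iter=3)
        assert len(exc.value.residual_history) > 1

    def test_current_conservation_across_a_plane(self):
        """Net normal current through a mid-plane of the conductor ~ 0."""
        head = cube_head(20, sigma=0.4)
        dadt = loop_dadt(head)
        sol = solve_potential(assemble_system(head, dadt), tol=1e-10)
        sigma = head.sigma_volume()
        k = 10
        sf = 2 * sigma[:, :, k - 1] * sigma[:, :, k] / np.maximum(
            sigma[:, :, k - 1] + sigma[:, :, k], 1e-30
        )
        h_m = head.voxel_size_mm * 1e-3
        e_face = -(sol.phi[:, :, k] - sol.phi[:, :, k - 1]) / h_m - 0.5 * (
            dadt[:, :, k - 1, 2] + dadt[:, :, k, 2]
        )
        total = np.sum(sf * e_face) * h_m**2
        through = np.sum(np.abs(sf * e_face)) * h_m**2
        assert abs(total) < 1e-6 * max(through, 1e-30)


class TestReconstruction:
    def test_intensity_scaling_is_exact(self):
        head = cube_head(12)
        dadt = loop_dadt(head)
        sol = solve_potential(assemble_system(head, dadt), tol=1e-8)
        ef100 = reconstruct_ef(sol, dadt, head, intensity_pct_mso=100.0)
        ef55 = reconstruct_ef(sol, dadt, head, intensity_pct_mso=55.0)
        assert np.allclose(ef55.E, 0.55 * ef100.E)
        assert np.allclose(ef100.scaled(55.0).E, ef55.E)

    def test_field_zero_outside_conductor(self):
        head = cube_head(12)
        dadt = loop_dadt(head)
        sol = solve_potential(assemble_system(head, dadt), tol=1e-8)
        ef = reconstruct_ef(sol, dadt, head)
        assert np.all(ef.E[~ef.conducting] == 0)
        assert np.all(np.isfinite(ef.E))


class TestSphericalOracles:
    def test_no_radial_field_in_homogeneous_sphere(self):
        """Induced E in a spherically symmetric conductor is tangential."""
        head = sphere_head(radius_mm=20.0, h=1.0)
        dadt = loop_dadt(head, loop_z_mm=35.0, radius_mm=25.0)
        sol = solve_potential(assemble_system(head, dadt), tol=1e-8)
        ef = reconstruct_ef(sol, dadt, head)
        centers = head.voxel_centers_world()
        mask = ef.conducting & (np.linalg.norm(centers, axis=-1) < 17.0)
        E = ef.E[mask]
        rhat = centers[mask] / np.linalg.norm(centers[mask], axis=1, keepdims=True)
        frac = np.abs(np.einsum("ij,ij->i", E, rhat)) / np.linalg.norm(E, axis=1)
        assert np.quantile(frac, 0.95) < 0.05

    def test_field_insensitive_to_radial_conductivity_profile(self):
        """Concentric layers do not change the induced field (up to
        discretization): homogeneous vs 3-layer sphere agree within 5%."""
        homog = sphere_head(radius_mm=20.0, h=1.0)
        layered = sphere_head(
            radius_mm=20.0, h=1.0, layers=[(1, 20.0), (2, 16.0), (4, 12.0)]
        )
        E = {}
        for name, head in (("homog", homog), ("layered", layered)):
            dadt = loop_dadt(head, loop_z_mm=35.0, radius_mm=25.0)
            sol = solve_potential(assemble_system(head, dadt), tol=1e-8)
            E[name] = reconstruct_ef(sol, dadt, head)
        centers = homog.voxel_centers_world()
        inner = (np.linalg.norm(centers, axis=-1) < 10.0) & E["homog"].conducting
        diff = np.linalg.norm(E["homog"].E[inner] - E["layered"].E[inner], axis=1)
        scale = np.linalg.norm(E["homog"].E[inner], axis=1).mean()
        assert diff.mean() / scale < 0.05


class TestGridConvergence:
    def test_max_cortical_field_stable_under_refinement(self):
        """Halving the voxel size (2 mm -> 1 mm) changes the peak cortical
        field by less than 5%."""
        from tmsmap.surface_metrics import sample_on_surface
        import tmsmap

        peaks = {}
        for vox in (2.0, 1.0):
            s = build_synthetic_head(HeadGeometry(voxel_size_mm=vox), seed=0)
            pls = tmsmap.placement_grid(
                s.sulcus_scalp_polyline(), projector=s.scalp_project
            )
            ef = solve_placement(
                s.head, CoilModel(), pls[13], intensity_pct_mso=100.0
            )
            m = sample_on_surface(ef, s.surface, "x", sample_mask=s.head.labels >= 4)
            peaks[vox] = m.ef_strength.max()
        assert abs(peaks[2.0] / peaks[1.0] - 1.0) < 0.05
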