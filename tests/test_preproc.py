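"""Velocity cleaning: temporal unwrap, normalized median test, lumen masking."""

import numpy as np
import pytest

from anewall import preproc, synthetic as syn
from anewall.core import VelocityField4D
from anewall.geometry import RigidTransform
from anewall.mesh import TriangleMesh


def single_voxel_series(values, venc=1.0):
    """Field with one signal voxel (1,1,1) carrying the given z-time series."""
    vel = np.zeros((len(values), 3, 3, 3, 3))
    vel[:, 1, 1, 1, 2] = values
    return VelocityField4D(origin=np.zeros(3), spacing=1.0, velocity=vel, venc=venc)


class TestUnwrapTemporal:
    def test_identity_without_wraps(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        f = single_voxel_series(0.5 + 0.3 * np.sin(t))
        out = preproc.unwrap_temporal(f)
        np.testing.assert_allclose(out.velocity, f.velocity, atol=1e-12)

    def test_single_wrap_round_trip(self, womersley_ica):
        """Peak ~1.9x VENC acquired wrapped is fully restored."""
        truth = womersley_ica
        _, acq = syn.make_pc_series(truth, venc=0.8, target_snr=np.inf, seed=1)
        assert np.abs(acq.velocity).max() <= 0.8 + 1e-12
        out = preproc.unwrap_temporal(acq)
        np.testing.assert_allclose(out.velocity, truth.velocity, atol=1e-9)
        assert out.unwrap_unresolved.sum() == 0

    def test_slow_double_wrap_restored_when_stepping_through(self):
        up = np.concatenate(
            [np.full(4, 0.2), np.linspace(0.2, 2.5, 7), np.full(3, 2.5),
             np.linspace(2.5, 0.2, 7)]
        )
        f = single_voxel_series(syn.wrap_velocity(up, 1.0))
        out = preproc.unwrap_temporal(f)
        np.testing.assert_allclose(out.velocity[:, 1, 1, 1, 2], up, atol=1e-12)

    def test_abrupt_return_flagged_unresolved(self):
        """A wrap crossed without detectable steps leaves a nonzero winding."""
        tv = np.concatenate(
            [np.full(4, 0.2), np.linspace(0.2, 2.5, 7), np.full(9, 2.5), [0.2]]
        )
        f = single_voxel_series(syn.wrap_velocity(tv, 1.0))
        out = preproc.unwrap_temporal(f)
        assert bool(out.unwrap_unresolved[1, 1, 1])

    def test_idempotent(self, womersley_ica):
        _, acq = syn.make_pc_series(womersley_ica, venc=0.8, target_snr=np.inf, seed=1)
        once = preproc.unwrap_temporal(acq)
        twice = preproc.unwrap_temporal(once)
        np.testing.assert_array_equal(once.velocity, twice.velocity)

    def test_requires_two_phases(self):
        f = single_voxel_series([0.5])
        with pytest.raises(ValueError):
            preproc.unwrap_temporal(f)


class TestMedianFilter:
    def test_uniform_field_no_flags(self):
        vel = np.full((2, 8, 8, 8, 3), 0.3)
        f = VelocityField4D(origin=np.zeros(3), spacing=0.5, velocity=vel, venc=1.1)
        _, rep = preproc.median_filter_outliers(f)
        assert rep.n_flagged == 0

    def test_spike_in_constant_field_replaced_by_constant(self):
        vel = np.full((1, 9, 9, 9, 3), 0.2)
        vel[0, 4, 4, 4] = 2.0  # 10x the neighbourhood
        f = VelocityField4D(origin=np.zeros(3), spacing=0.5, velocity=vel, venc=1.1)
        out, rep = preproc.median_filter_outliers(f, plane_axis=2)
        assert rep.n_flagged == 1
        np.testing.assert_allclose(out.velocity[0, 4, 4, 4], 0.2, atol=1e-12)

    def test_matches_brute_force_oracle_on_noise(self):
        """Flag set equals a naive double-loop reimplementation, voxel for voxel."""
        rng = np.random.default_rng(0)
        vel = rng.normal(0, 0.1, (2, 16, 16, 16, 3))
        f = VelocityField4D(origin=np.zeros(3), spacing=0.5, velocity=vel, venc=1.1)
        _, rep = preproc.median_filter_outliers(f, plane_axis=2)
        eps = 0.05 * 1.1
        oracle = set()
        for p in range(2):
            for i in range(16):
                for j in range(16):
                    for k in range(16):
                        nbs = [
                            vel[p, i + di, j + dj, k]
                            for di in (-1, 0, 1)
                            for dj in (-1, 0, 1)
                            if not (di == dj == 0)
                            and 0 <= i + di < 16
                            and 0 <= j + dj < 16
                        ]
                        if len(nbs) < 3:
                            continue
                        nbs = np.array(nbs)
                        m = np.median(nbs, axis=0)
                        r_med = np.median(np.abs(nbs - m), axis=0)
                        if np.max(np.abs(vel[p, i, j, k] - m) / (r_med + eps)) > 1:
                            oracle.add((p, i, j, k))
        mine = {
            (p, *map(int, idx)) for p in range(2) for idx in rep.flagged[p]
        }
        assert mine == oracle

    def test_second_pass_flags_subset_of_first(self):
        rng = np.random.default_rng(7)
        grid = syn.GridSpec.for_tube(5.0, 10.0, spacing=0.5)
        f = syn.sample_poiseuille(grid, 10.0, 5.0, n_phases=2)
        vel = f.velocity + rng.normal(0, 0.004, f.velocity.shape)
        spikes = rng.random(f.velocity.shape[:4]) < 0.01
        vel[..., 2][spikes] += 0.8
        fld = VelocityField4D(origin=f.origin, spacing=f.spacing, velocity=vel,
                              venc=1.1, lumen_mask=f.lumen_mask)
        f1, r1 = preproc.median_filter_outliers(fld)
        f2, r2 = preproc.median_filter_outliers(f1)
        s1 = {(p, *map(int, i)) for p in range(2) for i in r1.flagged[p]}
        s2 = {(p, *map(int, i)) for p in range(2) for i in r2.flagged[p]}
        assert s2 <= s1
        # every injected lumen spike is caught
        injected = {
            (p, *map(int, i))
            for p in range(2)
            for i in np.argwhere(spikes[p] & fld.lumen_mask)
        }
        assert injected <= s1

    def test_modifies_only_flagged_voxels(self):
        rng = np.random.default_rng(3)
        vel = rng.normal(0, 0.05, (1, 10, 10, 10, 3))
        f = VelocityField4D(origin=np.zeros(3), spacing=0.5, velocity=vel, venc=1.1)
        out, rep = preproc.median_filter_outliers(f, plane_axis=2)
        changed = np.argwhere(np.any(out.velocity[0] != vel[0], axis=-1))
        flagged = {tuple(map(int, i)) for i in rep.flagged[0]}
        assert {tuple(map(int, c)) for c in changed} <= flagged


class TestMaskLumen:
    def test_voxel_count_matches_cylinder_volume(self, tube, poiseuille_05):
        mesh, _ = tube
        masked = preproc.mask_lumen(poiseuille_05, mesh)
        vol_voxels = np.pi * 1.675**2 * 20.0 / 0.5**3
        shell = mesh.area() * 0.5 / 0.5**3  # one surface-voxel shell
        assert abs(masked.lumen_mask.sum() - vol_voxels) < shell

    def test_surface_outside_grid_errors(self, tube, poiseuille_05):
        mesh, _ = tube
        far = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            preproc.mask_lumen(poiseuille_05, mesh, far)

    def test_open_surface_rejected(self, tube, poiseuille_05):
        mesh, _ = tube
        opened = mesh.submesh(np.arange(mesh.n_faces) > 10)
        with pytest.raises(ValueError):
            preproc.mask_lumen(poiseuille_05, opened)

    def test_point_in_surface_agrees_with_signed_distance(self, tube):
        mesh, _ = tube
        rng = np.random.default_rng(1)
        pts = rng.uniform([-2.5, -2.5, -11], [2.5, 2.5, 11], (1000, 3))
        inside = mesh.contains(pts)
        sd = np.maximum(
            np.linalg.norm(pts[:, :2], axis=1) - 1.675, np.abs(pts[:, 2]) - 10.0
        )
        clear = np.abs(sd) > 0.15  # skip the faceting shell
        assert np.array_equal(inside[clear], sd[clear] < 0)

    def test_mask_invariant_under_joint_rigid_motion(self, tube):
        mesh, _ = tube
        grid = syn.GridSpec.for_tube(1.675, 20.0, spacing=0.5)
        f = syn.sample_poiseuille(grid, 4.38, 1.675)
        base = preproc.mask_lumen(f, mesh)
        # rotating surface and grid together must not change the mask:
        # apply T to the surface and express the field on the T-moved grid
        tr = RigidTransform.from_euler([0, 0, 30.0], [0.3, -0.2, 0.1])
        moved_mesh = TriangleMesh(tr.apply(mesh.vertices), mesh.faces.copy())
        # the voxel lattice moves with the transform, so containment per
        # voxel centre is unchanged; emulate by testing the same centres
        centres = f.voxel_centers().reshape(-1, 3)
        inside_orig = mesh.contains(centres)
        inside_moved = moved_mesh.contains(tr.apply(centres))
        assert np.mean(inside_orig != inside_moved) < 5e-3
        assert base.lumen_mask.sum() == inside_orig.sum()
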