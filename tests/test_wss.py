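"""Wall shear stress estimation: normals, the 4-point normal-line derivative,
TAWSS, OSI, and their analytic pipe-flow oracles."""

import numpy as np
import pytest

from anewall import synthetic as syn, wss as ws
from anewall.core import BLOOD_ANALOGUE, VelocityField4D
from anewall.wss import WSSRecord, WallBasis

from .conftest import Q_REF, TUBE_RADIUS

MU = BLOOD_ANALOGUE.dynamic_viscosity


def ring_basis(radius, n_pts=64, zs=(0.0,)):
    """Wall points on the tube with exact inward radial frames."""
    th = 2 * np.pi * np.arange(n_pts) / n_pts
    pts, nrm, t1, t2 = [], [], [], []
    for z in zs:
        for t in th:
            p = np.array([radius * np.cos(t), radius * np.sin(t), z])
            n = np.array([-np.cos(t), -np.sin(t), 0.0])
            a = np.array([-np.sin(t), np.cos(t), 0.0])
            pts.append(p)
            nrm.append(n)
            t1.append(a)
            t2.append(np.cross(n, a))
    arr = lambda x: np.array(x)
    return WallBasis(arr(pts), arr(nrm), arr(t1), arr(t2), np.ones(len(pts), bool))


def record_from_series(series):
    """WSSRecord with one vertex carrying the given (T, 3) WSS series."""
    w = np.asarray(series, float)[:, None, :]
    basis = WallBasis(
        points=np.zeros((1, 3)),
        normals=np.array([[0.0, 0.0, 1.0]]),
        t1=np.array([[1.0, 0.0, 0.0]]),
        t2=np.array([[0.0, 1.0, 0.0]]),
        valid=np.ones(1, bool),
    )
    return WSSRecord(wss=w, basis=basis, dt_ms=49.0, valid=np.ones(1, bool))


class TestPcaNormals:
    def test_plane_points_give_exact_plane_normal(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, 500), rng.uniform(-5, 5, 500), np.zeros(500)])
        basis = ws.pca_normals(pts, lumen_test=lambda p: p[:, 2] < 0)  # lumen below
        np.testing.assert_allclose(basis.normals, [[0, 0, -1.0]] * 500, atol=1e-12)

    def test_sphere_normals_radial_within_2_degrees(self):
        rng = np.random.default_rng(0)
        th = np.arccos(1 - 2 * rng.random(2000))
        ph = 2 * np.pi * rng.random(2000)
        pts = np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        basis = ws.pca_normals(pts, k=20, lumen_test=lambda p: np.linalg.norm(p, axis=1) < 1)
        cosang = np.sum(basis.normals * (-pts), axis=1)
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.all(cosang > 0)  # all inward
        assert ang.mean() < 2.0
        assert np.percentile(ang, 95) < 3.0

    def test_right_handed_orthonormal_frames(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(300, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        b = ws.pca_normals(pts, k=10, lumen_test=lambda p: np.linalg.norm(p, axis=1) < 1)
        for u, v in [(b.t1, b.t2), (b.t1, b.normals), (b.t2, b.normals)]:
            assert np.abs(np.sum(u * v, axis=1)).max() < 1e-10
        np.testing.assert_allclose(np.cross(b.t1, b.t2), b.normals, atol=1e-10)

    def test_collinear_neighbourhood_flagged(self):
        line = np.column_stack([np.linspace(0, 1, 30), np.zeros(30), np.zeros(30)])
        basis = ws.pca_normals(line, k=5, lumen_test=lambda p: np.ones(len(p), bool))
        assert not basis.valid.all()


class TestWssAtVertex:
    def test_poiseuille_exact_with_analytic_samples(self, poiseuille_05):
        """The cubic interpolant reproduces the parabolic profile exactly."""
        gt = poiseuille_05.ground_truth
        p = np.array([TUBE_RADIUS, 0.0, 0.0])
        n = np.array([-1.0, 0.0, 0.0])
        t1 = np.array([0.0, 1.0, 0.0])
        w = ws.wss_at_vertex(gt["sampler"], p, n, t1, np.cross(n, t1), MU)
        assert np.linalg.norm(w) == pytest.approx(gt["wss_pa"], rel=1e-9)
        assert np.linalg.norm(w) == pytest.approx(6.33, abs=0.005)

    def test_zero_field_zero_vector(self):
        grid = syn.GridSpec.for_tube(TUBE_RADIUS, 6.0)
        f = syn.sample_poiseuille(grid, 0.0, TUBE_RADIUS)
        w = ws.wss_at_vertex(
            f, np.array([TUBE_RADIUS, 0, 0.0]), np.array([-1.0, 0, 0]),
            np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), MU,
        )
        np.testing.assert_array_equal(w, 0.0)

    def test_womersley_time_series_within_5pct_rms(self):
        """Signed wall shear vs the Bessel closed form over the cycle."""
        wf = syn.make_ica_waveform(Q_REF)
        grid = syn.GridSpec.for_tube(TUBE_RADIUS, 4.0, spacing=0.1)
        f = syn.sample_womersley(grid, wf, TUBE_RADIUS)
        p = np.array([TUBE_RADIUS, 0.0, 0.0])
        n = np.array([-1.0, 0.0, 0.0])
        t1 = np.array([0.0, 1.0, 0.0])
        est = np.array(
            [
                ws.wss_at_vertex(f, p, n, t1, np.cross(n, t1), MU, phase=ph)[2]
                for ph in range(f.n_phases)
            ]
        )
        tau = f.ground_truth["wall_shear_pa"]
        rms = lambda x: np.sqrt(np.mean(np.square(x)))
        assert rms(est - tau) / rms(tau) < 0.05


class TestWssField:
    def test_steady_tube_spatially_uniform(self, poiseuille_05):
        basis = ring_basis(TUBE_RADIUS, zs=(-3.0, 0.0, 3.0))
        rec = ws.wss_field(poiseuille_05, basis, MU,
                           sampler=poiseuille_05.ground_truth["sampler"])
        mags = rec.magnitudes()[0]
        assert mags.std() / mags.mean() < 0.03

    def test_uniform_field_mean_equals_max(self, poiseuille_05):
        basis = ring_basis(TUBE_RADIUS)
        rec = ws.wss_field(poiseuille_05, basis, MU,
                           sampler=poiseuille_05.ground_truth["sampler"])
        assert rec.spatial_max[0] == pytest.approx(rec.spatial_mean[0], rel=1e-9)

    def test_tangency_invariant(self, womersley_ica):
        basis = ring_basis(TUBE_RADIUS, n_pts=32)
        rec = ws.wss_field(womersley_ica, basis, MU)
        dots = np.einsum("pvd,vd->pv", rec.wss, basis.normals)
        assert np.abs(dots).max() < 1e-10 * max(1.0, rec.magnitudes().max())

    def test_too_many_flagged_vertices_errors(self, poiseuille_05):
        basis = ring_basis(TUBE_RADIUS, zs=(0.0, 500.0))  # half outside the grid
        with pytest.raises(RuntimeError):
            ws.wss_field(poiseuille_05, basis, MU)

    def test_resolution_bias_decreases_monotonically(self):
        """The estimate is biased low on coarse grids and improves on refinement."""
        truth = None
        means = []
        for spacing in (0.5, 0.25, 0.1):
            grid = syn.GridSpec.for_tube(TUBE_RADIUS, 4.0, spacing=spacing)
            f = syn.sample_poiseuille(grid, Q_REF, TUBE_RADIUS)
            truth = f.ground_truth["wss_pa"]
            basis = ring_basis(TUBE_RADIUS, n_pts=48)
            rec = ws.wss_field(f, basis, MU)
            means.append(rec.magnitudes()[0].mean())
        assert means[0] < means[1] < means[2] < truth * 1.02
        assert means[2] == pytest.approx(truth, rel=0.02)


class TestTawssOsi:
    def test_constant_series_tawss_is_itself_osi_zero(self):
        w = np.array([0.4, 0.1, 0.0])
        rec = record_from_series(np.tile(w, (8, 1)))
        vec, mag = ws.tawss(rec)
        np.testing.assert_allclose(vec[0], w, atol=1e-14)
        assert ws.osi(rec)[0] == pytest.approx(0.0, abs=1e-14)

    def test_fully_reversing_series_tawss_zero_osi_half(self):
        w = np.array([1.0, 0.0, 0.0])
        rec = record_from_series([w, -w])
        _, mag = ws.tawss(rec)
        assert mag[0] == pytest.approx(0.0, abs=1e-14)
        assert ws.osi(rec)[0] == pytest.approx(0.5, abs=1e-14)

    def test_sinusoid_with_dc_offset(self):
        t = np.arange(21) / 21.0
        c = np.array([0.5, -0.2, 0.1])
        series = c[None] + np.array([1.0, 0, 0])[None] * np.sin(2 * np.pi * t)[:, None]
        rec = record_from_series(series)
        _, mag = ws.tawss(rec)
        assert mag[0] == pytest.approx(np.linalg.norm(c), rel=0.005)

    def test_zero_mean_sinusoid_osi_half(self):
        t = np.arange(21) / 21.0
        series = np.array([1.0, 0, 0])[None] * np.sin(2 * np.pi * t)[:, None]
        assert ws.osi(record_from_series(series))[0] == pytest.approx(0.5, abs=1e-6)

    def test_dead_vertex_osi_undefined_not_zero(self):
        rec = record_from_series(np.zeros((5, 3)))
        assert np.isnan(ws.osi(rec)[0])

    def test_osi_bounds_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            series = rng.normal(size=(21, 3))
            o = ws.osi(record_from_series(series))[0]
            assert 0.0 <= o <= 0.5
        # triangle inequality: |mean vector| <= mean magnitude
        rec = record_from_series(rng.normal(size=(21, 3)))
        vec, mag = ws.tawss(rec)
        assert mag[0] <= np.linalg.norm(rec.wss[:, 0], axis=1).mean() + 1e-12


class TestOsiWssColocation:
    def test_high_osi_sits_in_low_tawss_decile(self):
        """Oscillating secondary flow: reversing-shear wall points are exactly
        the low-TAWSS ones (vortex-tip pattern restated on a phantom)."""
        R = TUBE_RADIUS
        n_ph = 21
        t = np.arange(n_ph) / n_ph

        def sampler(pts, phase):
            # recirculation cell localized around theta = pi: shear there is
            # purely oscillatory (reversing), elsewhere steady forward flow
            r = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
            th = np.arctan2(pts[:, 1], pts[:, 0])
            prof = np.clip(1 - (r / R) ** 2, 0, None)
            dth = np.angle(np.exp(1j * (th - np.pi)))
            bump = np.exp(-((dth / 0.25) ** 2))
            steady = 1.0 - 0.98 * bump
            osc = bump * np.cos(2 * np.pi * t[phase])
            out = np.zeros((len(pts), 3))
            out[:, 2] = prof * (steady + osc)
            return out

        grid = syn.GridSpec.for_tube(R, 4.0, spacing=0.25)
        field = VelocityField4D(
            origin=np.array(grid.origin), spacing=grid.spacing,
            velocity=np.zeros((n_ph,) + grid.shape + (3,)), venc=1.1,
        )
        basis = ring_basis(R, n_pts=96)
        rec = ws.wss_field(field, basis, MU, sampler=sampler)
        _, tmag = ws.tawss(rec)
        o = ws.osi(rec)
        high_osi = np.flatnonzero(o > 0.2)
        low_decile = np.argsort(tmag)[: max(1, len(tmag) // 10)]
        assert len(high_osi) > 0
        assert set(high_osi) <= set(low_decile)
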