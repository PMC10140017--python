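"""Vessel geometry: centerline, registration, sac isolation, neck plane, morphometrics."""

import warnings

import numpy as np
import pytest

from anewall import geometry as geo, synthetic as syn
from anewall.geometry import RigidTransform
from anewall.mesh import TriangleMesh


def torus_segment(r_major=10.0, r_tube=1.5, n_u=80, n_v=24) -> TriangleMesh:
    """Watertight 90-degree bend used as the curved-vessel oracle."""
    u = np.linspace(0, np.pi / 2, n_u)
    v = 2 * np.pi * np.arange(n_v) / n_v
    verts, faces = [], []
    for uu in u:
        cdir = np.array([np.cos(uu), np.sin(uu), 0.0])
        cen = r_major * cdir
        for vv in v:
            verts.append(cen + r_tube * np.cos(vv) * cdir + r_tube * np.sin(vv) * np.array([0, 0, 1.0]))
    for i in range(n_u - 1):
        for j in range(n_v):
            jn = (j + 1) % n_v
            a, b = i * n_v + j, i * n_v + jn
            c, d = (i + 1) * n_v + j, (i + 1) * n_v + jn
            faces += [[a, b, c], [b, d, c]]
    c0, c1 = len(verts), len(verts) + 1
    verts += [r_major * np.array([1.0, 0, 0]), r_major * np.array([0, 1.0, 0])]
    for j in range(n_v):
        jn = (j + 1) % n_v
        faces += [[c0, jn, j], [c1, (n_u - 1) * n_v + j, (n_u - 1) * n_v + jn]]
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


class TestCenterline:
    def test_straight_tube_axis_and_diameter(self, tube):
        mesh, _ = tube
        cl = geo.compute_centerline(mesh, [0, 0, -9.5], [0, 0, 9.5])
        off_axis = np.linalg.norm(cl.points[:, :2], axis=1)
        assert off_axis.max() < 0.2
        s = cl.arclength
        mid = (s > 3) & (s < s[-1] - 3)  # away from the cap-influenced ends
        assert cl.diameters[mid] == pytest.approx(2 * 1.675, rel=0.05)

    def test_bend_arclength_matches_quarter_circle(self):
        mesh = torus_segment()
        cl = geo.compute_centerline(
            mesh, 10.0 * np.array([1.0, 0, 0]), 10.0 * np.array([0, 1.0, 0])
        )
        assert cl.length == pytest.approx(np.pi / 2 * 10.0, rel=0.05)

    def test_centerline_avoids_attached_sac(self, sphere_on_tube):
        mesh, _ = sphere_on_tube
        cl = geo.compute_centerline(mesh, [0, 0, -9.5], [0, 0, 9.5])
        assert np.linalg.norm(cl.points[:, :2], axis=1).max() < 0.5

    def test_endpoint_far_from_lumen_rejected(self, tube):
        mesh, _ = tube
        with pytest.raises(ValueError):
            geo.compute_centerline(mesh, [50.0, 0, 0], [0, 0, 9.5])


class TestRegistration:
    @pytest.fixture(scope="class")
    def speed_image(self):
        grid = syn.GridSpec.for_tube(1.675, 20.0, spacing=0.5, margin=4.0)
        return syn.sample_poiseuille(grid, 4.38, 1.675)

    def test_aligned_phantom_recovers_identity(self, tube, speed_image):
        mesh, _ = tube
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tr, _ = geo.register_rigid(mesh, speed_image)
        # tube is axisymmetric: rotation about z is a gauge freedom
        assert np.abs(tr.translation[:2]).max() < 0.05
        assert np.abs(tr.euler_deg()[:2]).max() < 0.1

    def test_known_perturbation_recovered(self, tube, speed_image):
        mesh, _ = tube
        true = RigidTransform.from_euler([0.0, 5.0, 0.0], [2.0, 0.0, 0.0])
        perturbed = TriangleMesh(true.inverse().apply(mesh.vertices), mesh.faces.copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tr, _ = geo.register_rigid(perturbed, speed_image)
        e = tr.euler_deg()
        assert e[1] == pytest.approx(5.0, abs=0.5)
        assert abs(e[0]) < 0.5
        assert tr.translation[0] == pytest.approx(2.0, abs=0.1)
        assert abs(tr.translation[1]) < 0.1

    def test_featureless_image_warns(self, tube):
        mesh, _ = tube
        img = np.ones((20, 20, 50))
        with pytest.warns(RuntimeWarning, match="flat|converge"):
            _, info = geo.register_rigid(mesh, (img, np.array([-5.0, -5.0, -12.0]), 0.5))
        assert not info["converged"]


class TestIsolateSac:
    def test_sac_area_matches_spherical_cap(self, sphere_on_tube):
        mesh, cl = sphere_on_tube
        iso = geo.isolate_sac(mesh, cl)
        assert iso.status == "ok"
        truth = mesh.metadata["ground_truth"]["sac_surface_mm2"]
        assert iso.sac.area() == pytest.approx(truth, rel=0.10)

    def test_plain_tube_leaves_nothing(self, tube):
        mesh, cl = tube
        iso = geo.isolate_sac(mesh, cl)
        assert iso.status == "empty"
        assert iso.sac.n_faces == 0

    def test_partition_of_original_faces(self, sphere_on_tube):
        mesh, cl = sphere_on_tube
        iso = geo.isolate_sac(mesh, cl)
        kept = (~iso.removed_faces).sum()
        assert kept + iso.removed_faces.sum() == mesh.n_faces
        assert iso.sac.n_faces <= kept

    def test_two_sacs_selected_by_rank(self):
        # two spheres fused on one tube at different z, different sizes
        tube_r, length = 1.7, 30.0
        pitch = 0.25
        margin = 3 * pitch
        big, small = 4.0, 2.5
        xs = np.arange(-tube_r - margin, tube_r + big * 2 + margin, pitch)
        ys = np.arange(-big - tube_r - margin, big + tube_r + margin, pitch)
        zs = np.arange(-length / 2 - margin, length / 2 + margin, pitch)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        f = np.sqrt(X**2 + Y**2) - tube_r
        f = np.minimum(f, np.sqrt((X - tube_r - big * 0.8) ** 2 + Y**2 + (Z + 7) ** 2) - big)
        f = np.minimum(f, np.sqrt((X - tube_r - small * 0.8) ** 2 + Y**2 + (Z - 7) ** 2) - small)
        f = np.maximum(f, np.abs(Z) - length / 2)
        from skimage import measure

        v, faces, _, _ = measure.marching_cubes(f, 0.0, spacing=(pitch,) * 3)
        mesh = TriangleMesh(v + np.array([xs[0], ys[0], zs[0]]), faces.astype(np.int64))
        n_cl = 101
        pts = np.zeros((n_cl, 3))
        pts[:, 2] = np.linspace(-length / 2, length / 2, n_cl)
        cl = geo.Centerline(pts, np.full(n_cl, 2 * tube_r))
        first = geo.isolate_sac(mesh, cl, rank=0)
        second = geo.isolate_sac(mesh, cl, rank=1)
        assert first.sac.area() > second.sac.area()
        # the large sac sits at z < 0, the small one at z > 0
        assert first.sac.vertices[:, 2].mean() < 0 < second.sac.vertices[:, 2].mean()


class TestNeckPlane:
    def test_coplanar_ring_exact(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), np.zeros_like(t)])
        plane = geo.fit_neck_plane(pts)
        assert plane.residual < 1e-12
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_jittered_ring_normal_within_2_degrees(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        for _ in range(20):
            pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), rng.normal(0, 0.1, len(t))])
            plane = geo.fit_neck_plane(pts)
            ang = np.degrees(np.arccos(min(1.0, abs(plane.normal @ [0, 0, 1]))))
            assert ang < 2.0

    def test_equals_principal_axes_oracle_on_saddle(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), 0.8 * np.cos(2 * t)])
        plane = geo.fit_neck_plane(pts)
        # independent oracle: brute-force search over plane orientations
        best, best_res = None, np.inf
        for th in np.linspace(0, np.pi, 60):
            for ph in np.linspace(0, 2 * np.pi, 120, endpoint=False):
                n = np.array(
                    [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
                )
                res = np.mean(((pts - pts.mean(0)) @ n) ** 2)
                if res < best_res:
                    best, best_res = n, res
        assert abs(plane.normal @ best) > np.cos(np.radians(3.0))

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            geo.fit_neck_plane(pts)


def hemisphere_mesh(a=4.0, n_u=60, n_v=120) -> tuple[TriangleMesh, np.ndarray]:
    """Open hemisphere of radius a (z >= 0) and its equator loop points."""
    verts = [[0.0, 0.0, a]]
    faces = []
    thetas = np.linspace(0, np.pi / 2, n_u)[1:]
    for i, th in enumerate(thetas):
        for j in range(n_v):
            ph = 2 * np.pi * j / n_v
            verts.append([a * np.sin(th) * np.cos(ph), a * np.sin(th) * np.sin(ph), a * np.cos(th)])
    for j in range(n_v):
        faces.append([0, 1 + j, 1 + (j + 1) % n_v])
    for i in range(len(thetas) - 1):
        base0, base1 = 1 + i * n_v, 1 + (i + 1) * n_v
        for j in range(n_v):
            jn = (j + 1) % n_v
            faces += [[base0 + j, base1 + j, base0 + jn], [base0 + jn, base1 + j, base1 + jn]]
    mesh = TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))
    equator = np.array(verts[1 + (len(thetas) - 1) * n_v :])
    return mesh, equator


class TestSacMorphometrics:
    def test_hemisphere_closed_forms(self):
        a = 4.0
        mesh, equator = hemisphere_mesh(a)
        plane = geo.fit_neck_plane(equator)
        m = geo.sac_morphometrics(mesh, plane, equator)
        assert m.perpendicular_height == pytest.approx(a, rel=0.01)
        assert m.neck_diameter == pytest.approx(2 * a, rel=0.01)
        assert m.aspect_ratio == pytest.approx(0.5, rel=0.02)
        assert m.volume == pytest.approx(2 * np.pi * a**3 / 3, rel=0.01)
        assert m.surface == pytest.approx(2 * np.pi * a**2, rel=0.01)
        assert m.max_width == pytest.approx(2 * a, rel=0.01)
        assert m.perpendicular_height <= m.max_height + 1e-9

    def test_flat_sac_degenerates_to_zero_height(self):
        mesh, equator = hemisphere_mesh(4.0)
        squashed = TriangleMesh(mesh.vertices * [1, 1, 0.02], mesh.faces.copy())
        plane = geo.fit_neck_plane(equator * [1, 1, 0.02])
        m = geo.sac_morphometrics(squashed, plane, equator * [1, 1, 0.02])
        assert m.perpendicular_height < 0.1
        assert m.aspect_ratio < 0.02

    def test_invariant_under_rigid_motion(self, sphere_on_tube):
        mesh, cl = sphere_on_tube
        iso = geo.isolate_sac(mesh, cl)
        plane = geo.fit_neck_plane(iso.neck_loop)
        m0 = geo.sac_morphometrics(iso.sac, plane, iso.neck_loop, cl)
        rng = np.random.default_rng(2)
        tr = RigidTransform.from_euler(rng.uniform(-40, 40, 3), rng.uniform(-7, 7, 3))
        sac_t = TriangleMesh(tr.apply(iso.sac.vertices), iso.sac.faces.copy())
        loop_t = tr.apply(iso.neck_loop)
        cl_t = geo.Centerline(tr.apply(cl.points), cl.diameters.copy())
        m1 = geo.sac_morphometrics(sac_t, geo.fit_neck_plane(loop_t), loop_t, cl_t)
        for k, v0 in m0.as_dict().items():
            assert m1.as_dict()[k] == pytest.approx(v0, rel=1e-6), k


class TestOrthogonalPlanes:
    def test_straight_tube_normals_equal_axis(self, tube):
        _, cl = tube
        frames = geo.orthogonal_planes(cl, 1.0)
        for fr in frames:
            ang = np.degrees(np.arccos(min(1.0, abs(fr.normal @ [0, 0, 1]))))
            assert ang < 0.5

    def test_station_count(self, tube):
        _, cl = tube
        assert len(geo.orthogonal_planes(cl, 1.2)) == int(np.floor(cl.length / 1.2)) + 1

    def test_sixteen_to_eighteen_planes_over_parent_artery(self, tube):
        """A ~17 mm parent segment at ~1 mm spacing gives 16-18 stations."""
        _, cl = tube
        sub = geo.Centerline(cl.points[cl.arclength <= 16.0], cl.diameters[cl.arclength <= 16.0])
        assert 16 <= len(geo.orthogonal_planes(sub, 1.0)) <= 18

    def test_torus_normals_match_analytic_tangents(self):
        mesh = torus_segment()
        cl = geo.compute_centerline(mesh, 10.0 * np.array([1.0, 0, 0]), 10.0 * np.array([0, 1.0, 0]))
        frames = geo.orthogonal_planes(cl, 2.0)
        for fr in frames:
            phi = np.arctan2(fr.center[1], fr.center[0])
            tan = np.array([-np.sin(phi), np.cos(phi), 0.0])
            ang = np.degrees(np.arccos(min(1.0, abs(fr.normal @ tan))))
            assert ang < 2.0

    def test_spacing_beyond_length_rejected(self, tube):
        _, cl = tube
        with pytest.raises(ValueError):
            geo.orthogonal_planes(cl, 100.0)
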