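"""Vessel and aneurysm geometry processing.

Covers surface smoothing, centerline extraction with local vessel diameter,
rigid co-registration of the segmented surface onto the velocity data, sac
isolation by the "remove everything within (D_vessel + 1 mm)/2 of the
centerline" rule, total-least-squares neck-plane fitting, sac morphometrics,
and centerline-orthogonal measurement planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage, sparse, interpolate, optimize
from scipy.spatial import ConvexHull, cKDTree

from .core import VelocityField4D
from .mesh import TriangleMesh, taubin_smooth  # noqa: F401  (re-exported)

__all__ = [
    "Centerline",
    "NeckPlane",
    "SacMorphometrics",
    "RigidTransform",
    "PlaneFrame",
    "SacIsolation",
    "taubin_smooth",
    "voxelize_surface",
    "compute_centerline",
    "register_rigid",
    "isolate_sac",
    "fit_neck_plane",
    "sac_morphometrics",
    "orthogonal_planes",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Ordered medial curve of the vessel with local diameter [mm]."""

    points: np.ndarray
    diameters: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.diameters) != len(self.points):
            raise ValueError("one diameter per point required")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def resample(self, spacing: float) -> "Centerline":
        s = self.arclength
        n = int(np.floor(s[-1] / spacing)) + 1
        si = np.arange(n) * spacing
        pts = np.column_stack(
            [np.interp(si, s, self.points[:, a]) for a in range(3)]
        )
        d = np.interp(si, s, self.diameters)
        return Centerline(pts, d)

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences along the polyline."""
        t = np.gradient(self.points, self.arclength, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


@dataclass
class NeckPlane:
    """Best-fit plane to the neck points (total least squares)."""

    normal: np.ndarray
    point: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        self.point = np.asarray(self.point, dtype=float)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal

    def in_plane_frame(self) -> tuple[np.ndarray, np.ndarray]:
        return _complete_frame(self.normal)


@dataclass
class SacMorphometrics:
    max_height: float
    perpendicular_height: float
    max_width: float
    volume: float
    surface: float
    neck_diameter: float
    aspect_ratio: float
    inlet_parent_diameter: float

    def as_dict(self) -> dict:
        return {
            "max_height_mm": self.max_height,
            "perpendicular_height_mm": self.perpendicular_height,
            "max_width_mm": self.max_width,
            "volume_mm3": self.volume,
            "surface_mm2": self.surface,
            "neck_diameter_mm": self.neck_diameter,
            "aspect_ratio": self.aspect_ratio,
            "inlet_parent_diameter_mm": self.inlet_parent_diameter,
        }


@dataclass
class RigidTransform:
    """Proper rigid motion: rotate about ``center`` then translate."""

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(
        cls, angles_deg: Sequence[float], translation: Sequence[float],
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        rx, ry, rz = np.deg2rad(angles_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, np.asarray(translation, float), np.asarray(center, float))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        return (p - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        # x' = R(x-c)+c+t  =>  x = R^T(x'-c-t)+c
        return RigidTransform(rinv, -rinv @ self.translation, self.center + self.translation)

    def euler_deg(self) -> np.ndarray:
        r = self.rotation
        ry = -np.arcsin(np.clip(r[2, 0], -1, 1))
        rx = np.arctan2(r[2, 1], r[2, 2])
        rz = np.arctan2(r[1, 0], r[0, 0])
        return np.rad2deg([rx, ry, rz])


def _complete_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangents completing a right-handed basis {t1, t2, n}."""
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(a, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


@dataclass
class PlaneFrame:
    """A measurement plane: centre, unit normal and an in-plane 2D frame."""

    center: np.ndarray
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    arclength: float = 0.0

    @classmethod
    def from_normal(cls, center, normal, arclength: float = 0.0) -> "PlaneFrame":
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        e1, e2 = _complete_frame(n)
        return cls(np.asarray(center, float), n, e1, e2, arclength)

    def raster(self, half_width: float, resolution: float):
        """(u, v) grid and 3-D sample points covering the plane patch."""
        u = np.arange(-half_width, half_width + resolution / 2, resolution)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        pts = (
            self.center[None, None]
            + uu[..., None] * self.e1[None, None]
            + vv[..., None] * self.e2[None, None]
        )
        return uu, vv, pts


@dataclass
class SacIsolation:
    sac: TriangleMesh
    neck_loop: np.ndarray  # ordered (M, 3) world points
    status: str  # "ok" | "empty"
    removed_faces: np.ndarray  # bool per original face


# ---------------------------------------------------------------------------
# Voxelisation (shared by centerline and lumen masking)
# ---------------------------------------------------------------------------

def voxelize_surface(
    surface: TriangleMesh,
    origin: np.ndarray,
    spacing: float,
    shape: tuple,
) -> np.ndarray:
    """Boolean interior mask on a cell-centred grid by z-column ray parity.

    Requires a watertight surface. Crossing parities are evaluated per
    (x, y) column, which makes the cost O(n_columns * n_faces).
    """
    if not surface.is_watertight():
        raise ValueError("voxelisation requires a watertight (closed) surface")
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)

    t = surface.triangles()
    ax, ay = t[:, 0, 0], t[:, 0, 1]
    bx, by = t[:, 1, 0], t[:, 1, 1]
    cx, cy = t[:, 2, 0], t[:, 2, 1]
    d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
    ok = np.abs(d) > 1e-30
    dsafe = np.where(ok, d, 1.0)

    mask = np.zeros(shape, dtype=bool)
    cols_x, cols_y = np.meshgrid(xs, ys, indexing="ij")
    cols = np.column_stack([cols_x.ravel(), cols_y.ravel()])
    chunk = max(1, int(2e7) // max(1, surface.n_faces))
    for s in range(0, len(cols), chunk):
        cxy = cols[s : s + chunk]
        px = cxy[:, 0][:, None]
        py = cxy[:, 1][:, None]
        w1 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / dsafe
        w2 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / dsafe
        w3 = 1.0 - w1 - w2
        hit = ok & (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        zhit = w1 * t[:, 0, 2] + w2 * t[:, 1, 2] + w3 * t[:, 2, 2]
        for row in range(len(cxy)):
            crossings = np.sort(zhit[row][hit[row]])
            if len(crossings) == 0:
                continue
            # inside iff an odd number of crossings lie above the sample
            above = len(crossings) - np.searchsorted(crossings, zs, side="right")
            col_mask = (above % 2) == 1
            i, j = divmod(s + row, ny)
            mask[i, j] = col_mask
    return mask


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to a triangle soup (exact, vectorised).

    Memory-bounded by chunking over points.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    chunk = max(1, int(5e6) // max(1, len(tri)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk][:, None, :]  # (P, 1, 3)
        ap = p - a[None]
        d1 = np.einsum("pfd,fd->pf", ap, ab)
        d2 = np.einsum("pfd,fd->pf", ap, ac)
        a11 = np.einsum("fd,fd->f", ab, ab)
        a12 = np.einsum("fd,fd->f", ab, ac)
        a22 = np.einsum("fd,fd->f", ac, ac)
        det = a11 * a22 - a12 * a12
        det = np.where(det < 1e-30, 1e-30, det)
        u = (a22 * d1 - a12 * d2) / det
        v = (a11 * d2 - a12 * d1) / det
        u = np.clip(u, 0.0, 1.0)
        v = np.clip(v, 0.0, 1.0)
        over = u + v > 1.0
        scale = np.where(over, 1.0 / np.where(u + v == 0, 1.0, u + v), 1.0)
        u = u * scale
        v = v * scale
        closest = a[None] + u[..., None] * ab[None] + v[..., None] * ac[None]
        dist = np.linalg.norm(p - closest, axis=2)
        out[s : s + chunk] = dist.min(axis=1)
    return out


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------

def compute_centerline(
    surface: TriangleMesh,
    source_point: np.ndarray,
    target_point: np.ndarray,
    voxel: float = 0.25,
    smoothing: float = 5.0,
    resample_mm: float = 0.25,
) -> Centerline:
    """Medial path between two lumen openings.

    The interior is voxelised; a distance-to-wall transform is computed; the
    shortest path between the endpoints under edge cost 1/(distance + eps)
    rides the medial ridge. The path is spline-smoothed and the local vessel
    diameter is measured as twice the exact distance to the surface.
    """
    source_point = np.asarray(source_point, float)
    target_point = np.asarray(target_point, float)
    lo, hi = surface.bounds()
    origin = lo - 2 * voxel
    shape = tuple(np.ceil((hi - lo + 4 * voxel) / voxel).astype(int) + 1)
    inside = voxelize_surface(surface, origin, voxel, shape)
    if not inside.any():
        raise ValueError("voxelised interior is empty; check the surface")
    dist = ndimage.distance_transform_edt(inside, sampling=voxel)

    idx = np.argwhere(inside)
    node_id = -np.ones(shape, dtype=np.int64)
    node_id[tuple(idx.T)] = np.arange(len(idx))
    dvals = dist[tuple(idx.T)]
    eps = 0.5 * voxel

    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    rows, cols, weights = [], [], []
    for off in offsets:
        shifted = idx + np.array(off)
        valid = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        nb = node_id[tuple(shifted[valid].T)]
        src = np.flatnonzero(valid)[nb >= 0]
        dst = nb[nb >= 0]
        step = voxel * np.linalg.norm(off)
        w = step * 0.5 * (1.0 / (dvals[src] + eps) + 1.0 / (dvals[dst] + eps))
        rows.append(src)
        cols.append(dst)
        weights.append(w)
    g = sparse.coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(idx), len(idx)),
    )

    def nearest_node(p: np.ndarray) -> int:
        world = origin + idx * voxel
        return int(np.argmin(np.linalg.norm(world - p, axis=1)))

    world = origin + idx * voxel
    for name, p in (("source", source_point), ("target", target_point)):
        if np.min(np.linalg.norm(world - p, axis=1)) > 5.0:
            raise ValueError(f"{name} point is more than 5 mm from the lumen")
    s_node = nearest_node(source_point)
    t_node = nearest_node(target_point)
    _, pred = sparse.csgraph.dijkstra(
        g, directed=False, indices=s_node, return_predecessors=True
    )
    if pred[t_node] < 0 and t_node != s_node:
        raise ValueError("endpoints are not connected inside the lumen")
    path = [t_node]
    while path[-1] != s_node:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    pts = world[path]

    if len(pts) >= 8:
        tck, _ = interpolate.splprep(pts.T, s=smoothing * len(pts) * voxel**2, k=3)
        u = np.linspace(0, 1, max(len(pts), int(np.ceil(30 / resample_mm))))
        pts = np.column_stack(interpolate.splev(u, tck))

    # ride the medial ridge: gradient-ascent each point on the smoothed
    # distance transform, restricted to the plane normal to the local tangent
    dist_s = ndimage.gaussian_filter(dist, sigma=1.0)
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # near the openings the distance ridge bends toward the caps; freeze there
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_par = np.concatenate([[0.0], np.cumsum(seg)])
    ramp = np.clip(np.minimum(s_par, s_par[-1] - s_par), 0.0, 1.0)[:, None]
    step = 0.4 * voxel
    for _ in range(25):
        ijk = ((pts - origin) / voxel).T
        grad = np.stack(
            [
                ndimage.map_coordinates(g, ijk, order=1, mode="nearest")
                for g in np.gradient(dist_s, voxel)
            ],
            axis=1,
        )
        grad -= np.einsum("id,id->i", grad, tang)[:, None] * tang
        gn = np.linalg.norm(grad, axis=1, keepdims=True)
        move = np.where(gn > 1e-6, grad / np.maximum(gn, 1e-12), 0.0)
        pts = pts + step * ramp * move * np.minimum(gn, 1.0)
        step *= 0.9

    # exact local diameter: twice the distance to the triangulated wall
    d_wall = _point_triangle_distance(pts, surface.triangles())
    d_wall = np.maximum(d_wall, 1e-6)
    cl = Centerline(pts, 2.0 * d_wall)
    return cl.resample(resample_mm)


# ---------------------------------------------------------------------------
# Rigid co-registration
# ---------------------------------------------------------------------------

def register_rigid(
    surface: TriangleMesh,
    reference: Union[VelocityField4D, tuple],
    initial: Optional[RigidTransform] = None,
    sample_spacing: float = 0.4,
    max_iter: int = 200,
) -> tuple[RigidTransform, dict]:
    """Align the segmented surface with a speed image by a quasi-Newton search.

    The objective is the mean reference intensity sampled (cubic spline) at
    fixed interior points of the surface; it is maximal when the surface
    encloses the bright lumen. ``reference`` is either a
    :class:`VelocityField4D` (its systolic speed volume is used) or a tuple
    ``(image, origin, spacing)``.

    Returns the optimal transform and an info dict with the objective trace
    and a convergence flag.
    """
    if isinstance(reference, VelocityField4D):
        means = [reference.mean_speed_in_mask(p) for p in range(reference.n_phases)]
        sys_phase = int(np.argmax(means))
        image = reference.speed(sys_phase)
        origin = reference.origin
        spacing = reference.spacing
    else:
        image, origin, spacing = reference
        origin = np.asarray(origin, float)

    lo, hi = surface.bounds()
    vshape = tuple(np.ceil((hi - lo + 4 * sample_spacing) / sample_spacing).astype(int) + 1)
    vorigin = lo - 2 * sample_spacing
    interior = voxelize_surface(surface, vorigin, sample_spacing, vshape)
    pts = vorigin + np.argwhere(interior) * sample_spacing
    center = pts.mean(axis=0)

    coeffs = ndimage.spline_filter(image, order=3)

    trace: list = []

    def objective(p: np.ndarray) -> float:
        tr = RigidTransform.from_euler(p[:3], p[3:], center=center)
        moved = tr.apply(pts)
        ijk = ((moved - origin) / spacing).T
        vals = ndimage.map_coordinates(
            coeffs, ijk, order=3, prefilter=False, mode="constant", cval=0.0
        )
        val = -float(vals.mean())
        trace.append(-val)
        return val

    p0 = np.zeros(6)
    if initial is not None:
        p0[:3] = initial.euler_deg()
        p0[3:] = initial.translation
    res = optimize.minimize(
        objective,
        p0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "eps": 1e-3, "ftol": 1e-12, "gtol": 1e-10},
    )
    if np.ptp(trace) < 1e-12:
        warnings.warn("flat registration objective (featureless reference image)",
                      RuntimeWarning)
        converged = False
    else:
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"registration did not converge ({res.message}); returning best-so-far",
                RuntimeWarning,
            )
    tr = RigidTransform.from_euler(res.x[:3], res.x[3:], center=center)
    info = {"objective_trace": trace, "converged": converged,
            "n_eval": len(trace), "final_objective": -float(res.fun)}
    return tr, info


# ---------------------------------------------------------------------------
# Sac isolation and morphometrics
# ---------------------------------------------------------------------------

def isolate_sac(
    surface: TriangleMesh,
    centerline: Centerline,
    margin_mm: float = 1.0,
    rank: int = 0,
) -> SacIsolation:
    """Remove the parent-vessel wall and keep the aneurysm sac.

    Every triangle whose centroid lies within a radius of
    ``(D_vessel(s*) + margin_mm) / 2`` of its nearest centerline point s* is
    removed; the sac is the ``rank``-th largest remaining connected component
    (by area) and its ordered boundary is the neck loop.
    """
    cl = centerline.resample(0.25) if centerline.length > 0.5 else centerline
    tree = cKDTree(cl.points)
    cent = surface.face_centroids()
    d, nearest = tree.query(cent)
    removal_r = (cl.diameters[nearest] + margin_mm) / 2.0
    keep = d > removal_r
    removed = ~keep
    if not keep.any():
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        return SacIsolation(empty, np.zeros((0, 3)), "empty", removed)

    sub = surface.submesh(keep)
    labels = sub.face_components()
    areas = sub.face_areas()
    comp_areas = np.bincount(labels, weights=areas)
    order = np.argsort(comp_areas)[::-1]
    if rank >= len(order):
        raise ValueError(f"only {len(order)} components; rank {rank} unavailable")
    sac = sub.submesh(labels == order[rank])
    loops = sac.boundary_loops()
    neck_loop = sac.vertices[loops[0]] if loops else np.zeros((0, 3))
    return SacIsolation(sac, neck_loop, "ok", removed)


def fit_neck_plane(points: np.ndarray) -> NeckPlane:
    """Orthogonal-regression plane through the neck points.

    Principal-axes total least squares: the plane passes through the centroid
    and its normal is the smallest-variance axis. The residual is the RMS
    orthogonal distance.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("points are collinear; plane is undefined")
    normal = vt[2]
    resid = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    return NeckPlane(normal=normal, point=centroid, residual=resid)


def sac_morphometrics(
    sac: TriangleMesh,
    neck_plane: NeckPlane,
    neck_loop: np.ndarray,
    centerline: Optional[Centerline] = None,
) -> SacMorphometrics:
    """Clinical sac metrics under the conventions documented in the methods note.

    perpendicular height: max distance of sac vertices from the neck plane on
    the sac side; max height: max distance from the neck-loop centroid to any
    sac vertex; max width: diameter of the sac's projection onto the neck
    plane; neck diameter: area-equivalent diameter of the projected neck
    loop; volume: sac closed by the planar neck cap (divergence theorem);
    aspect ratio: perpendicular height / neck diameter.
    """
    if sac.n_faces == 0:
        raise ValueError("empty sac")
    loops = sac.boundary_loops()
    if len(loops) != 1:
        raise ValueError(
            f"sac boundary has {len(loops)} loops; cannot close with a single neck cap"
        )
    # orient the plane normal toward the sac
    n = neck_plane.normal.copy()
    side = np.mean((sac.vertices - neck_plane.point) @ n)
    if side < 0:
        n = -n
    dist_plane = (sac.vertices - neck_plane.point) @ n
    perp_height = float(np.max(dist_plane))

    neck_centroid = np.asarray(neck_loop, float).mean(axis=0)
    max_height = float(np.max(np.linalg.norm(sac.vertices - neck_centroid, axis=1)))

    t1, t2 = _complete_frame(n)
    proj = np.column_stack(
        [(sac.vertices - neck_plane.point) @ t1, (sac.vertices - neck_plane.point) @ t2]
    )
    hull = ConvexHull(proj)
    hp = proj[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    max_width = float(np.sqrt((diff**2).sum(-1)).max())

    lp = np.column_stack(
        [(neck_loop - neck_plane.point) @ t1, (neck_loop - neck_plane.point) @ t2]
    )
    a_neck = 0.5 * abs(
        np.sum(lp[:, 0] * np.roll(lp[:, 1], -1) - np.roll(lp[:, 0], -1) * lp[:, 1])
    )
    neck_diameter = float(2.0 * np.sqrt(a_neck / np.pi))

    # volume of the sac closed by the neck cap: with the origin at the neck
    # centroid the planar cap fan contributes zero signed volume
    v = sac.vertices - neck_centroid
    t = v[sac.faces]
    volume = float(
        abs(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)
    )
    surface_area = sac.area()
    if centerline is not None:
        # proximal diameter, clear of the opening where distance-to-wall is
        # contaminated by the inlet cut plane
        s = centerline.arclength
        i0 = int(np.argmax(s >= min(1.5, s[-1] / 4)))
        inlet_d = float(centerline.diameters[i0])
    else:
        inlet_d = float("nan")
    return SacMorphometrics(
        max_height=max_height,
        perpendicular_height=perp_height,
        max_width=max_width,
        volume=volume,
        surface=surface_area,
        neck_diameter=neck_diameter,
        aspect_ratio=perp_height / neck_diameter,
        inlet_parent_diameter=inlet_d,
    )


# ---------------------------------------------------------------------------
# Measurement planes
# ---------------------------------------------------------------------------

def orthogonal_planes(
    centerline: Centerline, spacing: float, half_width: float = 3.0,
    end_margin: float = 0.0,
) -> list[PlaneFrame]:
    """Equally spaced centerline-orthogonal plane frames.

    Stations sit at arclengths 0, spacing, 2*spacing, ... (count
    floor(L/spacing) + 1); each plane's normal is the spline-smoothed local
    tangent and carries an in-plane orthonormal 2D frame of the given
    half-width. ``end_margin`` excludes stations within that distance of
    either centerline end (where an opening cut plane would clip the
    cross-section).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > centerline.length:
        raise ValueError("spacing exceeds the centerline length")
    cl = centerline
    s = cl.arclength
    n_st = int(np.floor(cl.length / spacing)) + 1
    stations = np.arange(n_st) * spacing
    if end_margin > 0:
        stations = stations[
            (stations >= end_margin) & (stations <= cl.length - end_margin)
        ]
        n_st = len(stations)

    if len(cl.points) >= 8:
        tck, u = interpolate.splprep(cl.points.T, u=s / s[-1], s=len(cl.points) * 0.01, k=3)
        pts = np.column_stack(interpolate.splev(stations / s[-1], tck))
        der = np.column_stack(interpolate.splev(stations / s[-1], tck, der=1))
    else:
        pts = np.column_stack([np.interp(stations, s, cl.points[:, a]) for a in range(3)])
        tans = cl.tangents()
        der = np.column_stack([np.interp(stations, s, tans[:, a]) for a in range(3)])
    frames = []
    for i in range(n_st):
        frames.append(PlaneFrame.from_normal(pts[i], der[i], arclength=float(stations[i])))
        frames[-1] = PlaneFrame(
            frames[-1].center, frames[-1].normal, frames[-1].e1, frames[-1].e2,
            float(stations[i]),
        )
    return frames
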