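"""Wall shear stress on the aneurysm sac, and its temporal descriptors.

For a Newtonian fluid the traction on the wall is sigma*n; its tangential
projection in the local wall basis B = {t1, t2, n} reduces, under the no-slip
condition (tangential derivatives of the normal velocity vanish at a fixed
wall), to

    WSS = mu * (d v_t1 / d xi3, d v_t2 / d xi3, 0)_B      [Pa]

with xi3 the inward-normal coordinate. The derivative at the wall is taken
from a cubic polynomial through 4 velocity samples along the inward normal
(xi3 = 0, 0.5, 1.0, 1.5 mm) with the wall sample forced to zero; a cubic is
the unique interpolant through 4 points and reproduces polynomial profiles
up to degree 3 (hence the parabolic Poiseuille profile) exactly.

TAWSS is the cycle time-average of the WSS *vector*; the oscillatory shear
index OSI = (1/2) * (1 - ||int WSS dt|| / int ||WSS|| dt) in [0, 0.5]
measures directional reversal (0: unidirectional, 0.5: fully reversing).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Callable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .core import VelocityField4D
from .mesh import TriangleMesh

__all__ = ["WallBasis", "WSSRecord", "pca_normals", "wss_at_vertex", "wss_field", "tawss", "osi"]

#: xi3 sample offsets along the inward normal [mm]
_XI3_MM = np.array([0.0, 0.5, 1.0, 1.5])

#: derivative at xi3=0 of the cubic through samples at 0, h, 2h, 3h (h = 0.5 mm)
_D0_COEFFS = np.array([-11.0, 18.0, -9.0, 2.0]) / (6.0 * 0.5)  # per mm


@dataclass
class WallBasis:
    """Per-point right-handed orthonormal frames {t1, t2, n} on the wall."""

    points: np.ndarray  # (V, 3) mm
    normals: np.ndarray  # (V, 3) inward unit normals
    t1: np.ndarray
    t2: np.ndarray
    valid: np.ndarray  # ambiguous-orientation points are excluded downstream


@dataclass
class WSSRecord:
    """Time-resolved WSS vectors on the sac wall plus summary statistics."""

    wss: np.ndarray  # (n_phases, V, 3) Pa, world coordinates
    basis: WallBasis
    dt_ms: float
    valid: np.ndarray  # (V,) vertices with all samples inside the grid
    spatial_max: np.ndarray = dfield(default=None)  # (n_phases,) Pa
    spatial_mean: np.ndarray = dfield(default=None)  # (n_phases,) Pa
    systolic_index: Optional[int] = None

    def __post_init__(self) -> None:
        mag = np.linalg.norm(self.wss, axis=-1)
        if self.spatial_max is None:
            self.spatial_max = mag[:, self.valid].max(axis=1) if self.valid.any() else np.zeros(len(mag))
        if self.spatial_mean is None:
            self.spatial_mean = mag[:, self.valid].mean(axis=1) if self.valid.any() else np.zeros(len(mag))

    @property
    def n_phases(self) -> int:
        return self.wss.shape[0]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.wss, axis=-1)


def pca_normals(
    points: np.ndarray,
    k: int = 20,
    lumen_test: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    surface: Optional[TriangleMesh] = None,
    delta: float = 0.1,
) -> WallBasis:
    """Inward wall normals from scattered wall points by local PCA.

    Each point's normal is the smallest-variance principal axis of its k
    nearest neighbours, oriented so that ``point + delta * n`` lies inside
    the lumen; ``lumen_test`` maps (N, 3) points to booleans (a watertight
    ``surface`` can be passed instead). Points whose neighbourhoods are
    degenerate or whose orientation is ambiguous (neither side inside) are
    marked invalid and excluded downstream.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} points")
    if lumen_test is None:
        if surface is None:
            raise ValueError("provide lumen_test or surface")
        lumen_test = surface.contains
    tree = cKDTree(pts)
    _, nb = tree.query(pts, k=k + 1)
    nb = nb[:, 1:]
    normals = np.empty_like(pts)
    valid = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        local = pts[nb[i]] - pts[nb[i]].mean(axis=0)
        _, s, vt = np.linalg.svd(local, full_matrices=False)
        if s[1] < 1e-9 * max(s[0], 1e-30):  # collinear neighbourhood
            valid[i] = False
            normals[i] = np.array([0.0, 0.0, 1.0])
            continue
        normals[i] = vt[2]
    probe_in = lumen_test(pts + delta * normals)
    probe_out = lumen_test(pts - delta * normals)
    flip = ~probe_in & probe_out
    normals[flip] = -normals[flip]
    ambiguous = ~probe_in & ~probe_out
    valid &= ~ambiguous

    t1 = np.empty_like(normals)
    t2 = np.empty_like(normals)
    for i in range(len(pts)):
        a = np.array([1.0, 0.0, 0.0]) if abs(normals[i, 0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v1 = np.cross(a, normals[i])
        v1 /= np.linalg.norm(v1)
        t1[i] = v1
        t2[i] = np.cross(normals[i], v1)
    return WallBasis(points=pts, normals=normals, t1=t1, t2=t2, valid=valid)


def wss_at_vertex(
    sampler: Union[VelocityField4D, Callable[[np.ndarray, int], np.ndarray]],
    point: np.ndarray,
    normal: np.ndarray,
    t1: np.ndarray,
    t2: np.ndarray,
    mu: float,
    phase: int = 0,
    normal_length: float = 1.5,
    n_samples: int = 4,
) -> np.ndarray:
    """WSS vector [Pa] at one wall point and cardiac phase, world coordinates.

    Velocities are sampled at xi3 = 0, 0.5, 1.0, 1.5 mm along the inward
    normal (the wall sample is forced to zero by the no-slip condition); each
    tangential component is differentiated at the wall through the 4-point
    cubic interpolant.
    """
    if n_samples != 4 or normal_length != 1.5:
        raise ValueError("the estimator is defined for 4 samples over 1.5 mm")
    fn = sampler.sampler() if isinstance(sampler, VelocityField4D) else sampler
    xi = _XI3_MM
    pts = np.asarray(point, float)[None] + xi[:, None] * np.asarray(normal, float)[None]
    v = fn(pts, phase)  # (4, 3) m/s
    v[0] = 0.0
    vt1 = v @ np.asarray(t1, float)
    vt2 = v @ np.asarray(t2, float)
    # d/dxi3 at the wall [1/s]: mm-grid derivative of m/s values -> (m/s)/mm = 1e3 1/s
    d1 = float(_D0_COEFFS @ vt1) * 1e3
    d2 = float(_D0_COEFFS @ vt2) * 1e3
    return mu * (d1 * np.asarray(t1, float) + d2 * np.asarray(t2, float))


def wss_field(
    field: VelocityField4D,
    basis: Union[WallBasis, TriangleMesh],
    mu: float,
    sampler: Optional[Callable[[np.ndarray, int], np.ndarray]] = None,
    systolic_index: Optional[int] = None,
    max_flagged_fraction: float = 0.2,
) -> WSSRecord:
    """WSS vectors at every sac wall point and cardiac phase.

    ``basis`` is a :class:`WallBasis` (or a sac mesh, in which case PCA
    normals are computed from its vertices oriented against the lumen mask).
    Vertices whose 1.5 mm normal ray leaves the grid are flagged and excluded
    from the per-phase spatial max/mean summaries; more than
    ``max_flagged_fraction`` flagged vertices raises (geometry or
    registration is then suspect).
    """
    if isinstance(basis, TriangleMesh):
        basis = pca_normals(basis.vertices, surface=basis)
    fn = field.sampler() if sampler is None else sampler
    pts = basis.points
    nvert = len(pts)
    xi = _XI3_MM
    sample_pts = pts[None, :, :] + xi[:, None, None] * basis.normals[None, :, :]
    flat = sample_pts.reshape(-1, 3)

    lo = field.origin - 0.5 * field.spacing
    hi = field.origin + (np.array(field.shape) - 0.5) * field.spacing
    in_grid = np.all((flat >= lo) & (flat <= hi), axis=1).reshape(4, nvert).all(axis=0)
    valid = basis.valid & in_grid
    frac_flagged = 1.0 - valid.sum() / nvert
    if frac_flagged > max_flagged_fraction:
        raise RuntimeError(
            f"{frac_flagged:.0%} of wall vertices flagged; geometry/registration suspect"
        )

    wss = np.zeros((field.n_phases, nvert, 3))
    for p in range(field.n_phases):
        v = fn(flat, p).reshape(4, nvert, 3)
        v[0] = 0.0
        vt1 = np.einsum("snd,nd->sn", v, basis.t1)
        vt2 = np.einsum("snd,nd->sn", v, basis.t2)
        d1 = np.einsum("s,sn->n", _D0_COEFFS, vt1) * 1e3
        d2 = np.einsum("s,sn->n", _D0_COEFFS, vt2) * 1e3
        wss[p] = mu * (d1[:, None] * basis.t1 + d2[:, None] * basis.t2)

    return WSSRecord(
        wss=wss, basis=basis, dt_ms=field.dt_ms, valid=valid,
        systolic_index=systolic_index,
    )


def tawss(record: WSSRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex time-averaged WSS vector and its magnitude [Pa].

    Rectangle-rule average over the uniform cardiac phases, cycle periodic.
    """
    vec = record.wss.mean(axis=0)
    return vec, np.linalg.norm(vec, axis=-1)


def osi(record: WSSRecord) -> np.ndarray:
    """Per-vertex oscillatory shear index in [0, 0.5]; NaN where undefined.

    OSI = 0.5 * (1 - ||mean_t WSS|| / mean_t ||WSS||), with the same
    rectangle-rule quadrature as TAWSS. A vertex where the WSS magnitude
    integral vanishes has no defined direction statistics and is reported as
    NaN rather than an arbitrary extreme.
    """
    vec_mean = np.linalg.norm(record.wss.mean(axis=0), axis=-1)
    mag_mean = np.linalg.norm(record.wss, axis=-1).mean(axis=0)
    out = np.full(vec_mean.shape, np.nan)
    ok = mag_mean > 0
    out[ok] = np.clip(0.5 * (1.0 - vec_mean[ok] / mag_mean[ok]), 0.0, 0.5)
    return out
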