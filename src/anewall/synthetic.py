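"""Synthetic flows, phantom geometries and PC-MRI-like acquisitions.

Everything downstream (unwrapping, masking, flow rates, WSS/OSI, SNR) is
validated against the ground truth carried by these generators:

* steady Poiseuille pipe flow with its closed-form wall shear 4*mu*Q/(pi R^3),
* pulsatile Womersley flow (Bessel-function profile per harmonic) with its
  closed-form wall-shear time series,
* a cylinder phantom and a sphere-on-tube aneurysm phantom with analytic
  neck/sac metrics,
* a fixed-shape pulsatile internal-carotid-artery waveform, and
* a phase-contrast acquisition model: constant lumen magnitude plus Gaussian
  noise, velocity encoded as phase pi*v/VENC, wrapped into (-pi, pi].

Defaults emulate the acquisition this package targets: 0.5 mm isotropic
voxels, 21 cardiac phases at 49 ms, VENC 1.1-1.2 m/s, a ~1 Hz pulsatile
waveform and a glycerine/water blood analogue (rho = 1142 kg/m^3,
nu = 4.67e-6 m^2/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import special
from skimage import measure

from .core import BLOOD_ANALOGUE, FlowWaveform, FluidProperties, MagnitudeSeries, VelocityField4D
from .geometry import Centerline
from .mesh import TriangleMesh

__all__ = [
    "GridSpec",
    "make_tube_phantom",
    "make_sphere_on_tube",
    "make_ica_waveform",
    "sample_poiseuille",
    "sample_womersley",
    "womersley_velocity_profile",
    "womersley_wall_shear",
    "make_pc_series",
    "wrap_velocity",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular cell-centred voxel grid: origin [mm], isotropic spacing [mm], shape."""

    origin: tuple
    spacing: float
    shape: tuple

    @classmethod
    def for_tube(
        cls, radius: float, length: float, spacing: float = 0.5, margin: float = 1.0
    ) -> "GridSpec":
        """Grid enclosing a z-axis tube of given radius/length plus a margin."""
        half_xy = radius + margin
        half_z = length / 2.0 + margin
        nxy = int(np.ceil(2 * half_xy / spacing)) + 1
        nz = int(np.ceil(2 * half_z / spacing)) + 1
        org = (-(nxy - 1) / 2.0 * spacing, -(nxy - 1) / 2.0 * spacing, -(nz - 1) / 2.0 * spacing)
        return cls(origin=org, spacing=spacing, shape=(nxy, nxy, nz))

    def coords(self):
        """Per-axis cell-centre coordinate vectors."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)
        )

    def meshgrid(self):
        x, y, z = self.coords()
        return np.meshgrid(x, y, z, indexing="ij")


# ---------------------------------------------------------------------------
# Phantom geometries
# ---------------------------------------------------------------------------

def make_tube_phantom(
    radius: float, length: float, mesh_pitch: float = 0.3
) -> tuple[TriangleMesh, Centerline]:
    """Watertight cylinder along z, centred at the origin, with end caps.

    Faces are labelled ``"wall"`` (lateral surface) and ``"cap"``; the
    centerline is the axis polyline with local diameter 2*radius everywhere.
    """
    if radius <= 0 or length <= 0 or mesh_pitch <= 0:
        raise ValueError("radius, length and mesh_pitch must be positive")
    n_theta = max(12, int(np.ceil(2 * np.pi * radius / mesh_pitch)))
    n_z = max(2, int(np.ceil(length / mesh_pitch)) + 1)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    zs = np.linspace(-length / 2.0, length / 2.0, n_z)

    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = np.concatenate(
        [np.column_stack([ring, np.full(n_theta, z)]) for z in zs]
    )
    faces = []
    for k in range(n_z - 1):
        base0 = k * n_theta
        base1 = (k + 1) * n_theta
        for t in range(n_theta):
            tn = (t + 1) % n_theta
            faces.append([base0 + t, base0 + tn, base1 + t])
            faces.append([base0 + tn, base1 + tn, base1 + t])
    n_wall = len(faces)
    # cap fans
    c_bot = len(verts)
    c_top = len(verts) + 1
    verts = np.concatenate([verts, [[0, 0, zs[0]], [0, 0, zs[-1]]]])
    for t in range(n_theta):
        tn = (t + 1) % n_theta
        faces.append([c_bot, tn, t])
        faces.append([c_top, (n_z - 1) * n_theta + t, (n_z - 1) * n_theta + tn])
    labels = np.array(["wall"] * n_wall + ["cap"] * (len(faces) - n_wall))
    mesh = TriangleMesh(verts, np.array(faces), face_labels=labels)
    mesh.metadata.update(
        {"kind": "tube", "radius_mm": radius, "length_mm": length}
    )

    n_cl = max(5, int(np.ceil(length / mesh_pitch)) + 1)
    pts = np.zeros((n_cl, 3))
    pts[:, 2] = np.linspace(-length / 2.0, length / 2.0, n_cl)
    cl = Centerline(points=pts, diameters=np.full(n_cl, 2 * radius))
    return mesh, cl


def make_sphere_on_tube(
    tube_radius: float,
    sac_radius: float,
    neck_radius: Optional[float] = None,
    length: float = 20.0,
    mesh_pitch: float = 0.2,
) -> tuple[TriangleMesh, Centerline]:
    """Tube with a spherical aneurysm sac fused on its +x side at z = 0.

    The sphere centre sits at distance ``sqrt(a^2 - b^2)`` outside the wall
    plane (a = sac radius, b = neck radius), so the neck opening is a circle
    of radius b.  The union surface is extracted by marching cubes from the
    implicit signed distance, hence watertight.  Ground-truth sac metrics
    (spherical-cap formulas) are stored in ``mesh.metadata["ground_truth"]``.
    """
    if tube_radius <= 0 or length <= 0 or mesh_pitch <= 0:
        raise ValueError("dimensions must be positive")
    if sac_radius == 0:
        return make_tube_phantom(tube_radius, length, mesh_pitch)
    if neck_radius is None:
        neck_radius = sac_radius
    if not (0 < neck_radius <= sac_radius):
        raise ValueError("require 0 < neck_radius <= sac_radius")

    a, b = float(sac_radius), float(neck_radius)
    hc = np.sqrt(a * a - b * b)  # sphere-centre height above the wall plane
    cx = tube_radius + hc
    if cx - a <= -tube_radius:
        warnings.warn(
            "sac sphere protrudes through the opposite tube wall; the fused "
            "surface may be degenerate (ground-truth metadata is still exact)",
            RuntimeWarning,
        )

    margin = 3 * mesh_pitch
    x0, x1 = -tube_radius - margin, cx + a + margin
    ye = max(tube_radius, a) + margin
    z0, z1 = -length / 2.0 - margin, length / 2.0 + margin
    xs = np.arange(x0, x1 + mesh_pitch, mesh_pitch)
    ys = np.arange(-ye, ye + mesh_pitch, mesh_pitch)
    zs = np.arange(z0, z1 + mesh_pitch, mesh_pitch)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    f_cyl = np.sqrt(X**2 + Y**2) - tube_radius
    f_sph = np.sqrt((X - cx) ** 2 + Y**2 + Z**2) - a
    # smooth union: a small fillet at the neck junction avoids the pinched
    # crease a hard min() would give marching cubes (and is anatomically
    # closer to a real neck than a sharp edge)
    s = 0.25  # mm fillet scale
    f = -s * np.logaddexp(-f_cyl / s, -f_sph / s)
    f = np.maximum(f, np.abs(Z) - length / 2.0)  # clip tube ends

    verts, faces, _, _ = measure.marching_cubes(
        f, level=0.0, spacing=(mesh_pitch,) * 3, allow_degenerate=False
    )
    verts = verts + np.array([xs[0], ys[0], zs[0]])
    mesh = TriangleMesh(verts, faces.astype(np.int64)).clean()

    cap_h = a + hc  # sac = spherical cap of height a + hc
    mesh.metadata.update(
        {
            "kind": "sphere_on_tube",
            "tube_radius_mm": tube_radius,
            "sac_radius_mm": a,
            "neck_radius_mm": b,
            "ground_truth": {
                "neck_center_mm": [float(tube_radius), 0.0, 0.0],
                "neck_normal": [1.0, 0.0, 0.0],
                "neck_radius_mm": b,
                "sac_surface_mm2": float(2 * np.pi * a * cap_h),
                "sac_volume_mm3": float(np.pi * cap_h**2 * (3 * a - cap_h) / 3.0),
                "sphere_center_mm": [float(cx), 0.0, 0.0],
            },
        }
    )
    n_cl = max(5, int(np.ceil(length / mesh_pitch)) + 1)
    pts = np.zeros((n_cl, 3))
    pts[:, 2] = np.linspace(-length / 2.0, length / 2.0, n_cl)
    cl = Centerline(points=pts, diameters=np.full(n_cl, 2 * tube_radius))
    return mesh, cl


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------

def make_ica_waveform(
    q_bar: float,
    f0: float = 1.0,
    n_phases: int = 21,
    dt_ms: Optional[float] = 49.0,
    peak_ratio: float = 1.65,
) -> FlowWaveform:
    """Pulsatile internal-carotid-artery-like waveform, rescaled to mean q_bar.

    The built-in shape is a band-limited (8 harmonics) von Mises systolic
    pulse with its peak at 12% of the cycle; the systolic peak/mean ratio is
    fixed (default 1.65, mid physiological range). When ``dt_ms`` is given,
    the period is ``n_phases * dt_ms`` (e.g. 21 x 49 ms = 1029 ms, emulating
    a ~1 s cardiac cycle on the acquisition grid); otherwise it is ``1/f0``.
    """
    if q_bar <= 0:
        raise ValueError("q_bar must be positive")
    if dt_ms is not None:
        period = n_phases * dt_ms * 1e-3
    else:
        period = 1.0 / f0
    times = np.arange(n_phases) * period / n_phases

    kappa, t_peak, n_h = 4.0, 0.12, 8
    # von Mises bump Fourier series: exp(k cos th) = I0 + 2 sum I_n cos(n th);
    # a Lanczos sigma taper removes the truncation ripple so the systolic
    # maximum is unique
    n_idx = np.arange(1, n_h + 1)
    taper = np.sinc(n_idx / (n_h + 1))
    i_n = special.iv(n_idx, kappa) * taper
    theta = 2 * np.pi * (times / period - t_peak)
    bump = 2 * np.sum(
        i_n[:, None] * np.cos(n_idx[:, None] * theta[None, :]), axis=0
    )
    bump -= bump.mean()  # exact zero mean on any phase grid (aliasing-safe)
    peak_excess = 2 * np.sum(i_n)  # value of `bump` at theta = 0
    q = q_bar * (1.0 + (peak_ratio - 1.0) * bump / peak_excess)
    return FlowWaveform(times=times, q=q)


# ---------------------------------------------------------------------------
# Analytic velocity fields
# ---------------------------------------------------------------------------

def _radial(grid: GridSpec):
    X, Y, Z = grid.meshgrid()
    return np.sqrt(X**2 + Y**2)


def sample_poiseuille(
    grid: GridSpec,
    q: float,
    radius: float,
    fluid: FluidProperties = BLOOD_ANALOGUE,
    n_phases: int = 1,
    dt_ms: float = 49.0,
    venc: float = 1.1,
) -> VelocityField4D:
    """Steady parabolic pipe flow u(r) = (2Q/pi R^2)(1 - r^2/R^2) along +z.

    Q in ml/s, radius in mm, velocities in m/s. Ground truth attached:
    the analytic wall shear 4*mu*Q/(pi R^3) [Pa], Q(t), and an analytic
    point sampler.
    """
    r_mm = float(radius)
    if r_mm <= 0:
        raise ValueError("radius must be positive")
    x, y, _ = grid.coords()
    if r_mm > max(x.max(), -x.min()) + 1e-9 or r_mm > max(y.max(), -y.min()) + 1e-9:
        raise ValueError("grid does not cover the lumen cross-section")

    u_max = 2.0 * q / (np.pi * r_mm**2)  # ml/s / mm^2 == m/s
    rr = _radial(grid)
    inside = rr < r_mm
    uz = np.where(inside, u_max * (1.0 - (rr / r_mm) ** 2), 0.0)
    vel = np.zeros((n_phases,) + grid.shape + (3,))
    vel[..., 2] = uz[None]

    mu = fluid.dynamic_viscosity
    wss_pa = 4.0 * mu * (q * 1e-6) / (np.pi * (r_mm * 1e-3) ** 3)

    def sampler(points_mm: np.ndarray, phase: int = 0) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
        out = np.zeros((len(p), 3))
        out[:, 2] = np.where(r < r_mm, u_max * (1 - (r / r_mm) ** 2), 0.0)
        return out

    return VelocityField4D(
        origin=np.array(grid.origin),
        spacing=grid.spacing,
        velocity=vel,
        venc=venc,
        dt_ms=dt_ms,
        lumen_mask=inside,
        ground_truth={
            "wss_pa": float(wss_pa),
            "q_ml_s": np.full(n_phases, q),
            "sampler": sampler,
            "radius_mm": r_mm,
            "u_max_m_s": float(u_max),
        },
    )


def _womersley_terms(
    harmonics: np.ndarray, radius_mm: float, fluid: FluidProperties, f0: float
):
    """Per-harmonic closed-form profile and wall-shear factors (SI units)."""
    R = radius_mm * 1e-3
    nu, mu = fluid.kinematic_viscosity, fluid.dynamic_viscosity
    w0 = 2 * np.pi * f0
    terms = []
    for n, c in enumerate(harmonics):
        qn = c * 1e-6  # ml/s -> m^3/s (complex amplitude)
        if n == 0:
            terms.append(("steady", qn.real))
            continue
        alpha_n = R * np.sqrt(n * w0 / nu)
        lam = alpha_n * np.exp(1j * 3 * np.pi / 4)  # i^(3/2) * alpha_n
        j0 = special.jv(0, lam)
        j1 = special.jv(1, lam)
        dn = 1.0 - 2.0 * j1 / (lam * j0)
        terms.append(("osc", qn, lam, j0, dn, n))
    return terms, R, mu, w0


def womersley_velocity_profile(
    r_mm: np.ndarray,
    t_s: float,
    harmonics: np.ndarray,
    radius_mm: float,
    fluid: FluidProperties = BLOOD_ANALOGUE,
    f0: float = 1.0,
) -> np.ndarray:
    """Axial velocity u(r, t) [m/s] of the closed-form pulsatile pipe solution.

    ``harmonics`` are complex flow-rate coefficients c_n [ml/s] such that
    Q(t) = Re(sum c_n exp(i n w0 t)); each harmonic's profile is normalised
    so its cross-section integral reproduces exactly its share of Q(t).
    """
    terms, R, _, w0 = _womersley_terms(np.asarray(harmonics, complex), radius_mm, fluid, f0)
    r = np.asarray(r_mm, dtype=float) * 1e-3
    xi = np.clip(r / R, 0.0, None)
    u = np.zeros_like(xi, dtype=float)
    inside = xi <= 1.0
    for term in terms:
        if term[0] == "steady":
            q0 = term[1]
            u = u + np.where(inside, 2.0 * q0 / (np.pi * R**2) * (1 - xi**2), 0.0)
        else:
            _, qn, lam, j0, dn, n = term
            prof = (qn / (np.pi * R**2)) * (1 - special.jv(0, lam * xi) / j0) / dn
            u = u + np.where(inside, (prof * np.exp(1j * n * w0 * t_s)).real, 0.0)
    return u


def womersley_wall_shear(
    t_s: np.ndarray,
    harmonics: np.ndarray,
    radius_mm: float,
    fluid: FluidProperties = BLOOD_ANALOGUE,
    f0: float = 1.0,
) -> np.ndarray:
    """Closed-form wall shear tau_w(t) [Pa], positive along +z flow.

    tau_w = -mu du/dr at r = R (the stress the fluid exerts on the wall,
    projected on the flow direction).
    """
    terms, R, mu, w0 = _womersley_terms(np.asarray(harmonics, complex), radius_mm, fluid, f0)
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    tau = np.zeros(len(t))
    for term in terms:
        if term[0] == "steady":
            tau = tau + 4.0 * mu * term[1] / (np.pi * R**3)
        else:
            _, qn, lam, j0, dn, n = term
            dudr = (qn / (np.pi * R**2)) * (lam / R) * special.jv(1, lam) / (j0 * dn)
            tau = tau + (-mu * dudr * np.exp(1j * n * w0 * t)).real
    return tau if np.ndim(t_s) else tau[0]


def sample_womersley(
    grid: GridSpec,
    waveform: Union[FlowWaveform, np.ndarray],
    radius: float,
    fluid: FluidProperties = BLOOD_ANALOGUE,
    n_phases: int = 21,
    dt_ms: float = 49.0,
    venc: float = 1.1,
    f0: Optional[float] = None,
    n_harmonics: int = 8,
) -> VelocityField4D:
    """Pulsatile Womersley flow along +z sampled on a voxel grid.

    ``waveform`` is either a :class:`FlowWaveform` (its harmonics and
    fundamental are used; phases are sampled at ``dt_ms`` over its period) or
    a complex harmonic array c_n [ml/s] with fundamental ``f0``.
    Ground truth attached: Q(t), the wall-shear time series and an analytic
    space-time sampler.
    """
    if isinstance(waveform, FlowWaveform):
        harmonics = waveform.harmonics(n_harmonics)
        f0 = waveform.f0
        n_phases = len(waveform.times)
        dt_ms = waveform.dt * 1e3
    else:
        harmonics = np.asarray(waveform, dtype=complex)
        if f0 is None:
            raise ValueError("f0 is required when passing raw harmonics")
    r_mm = float(radius)
    alpha = (r_mm * 1e-3) * np.sqrt(2 * np.pi * f0 / fluid.kinematic_viscosity)
    if alpha > 20:
        warnings.warn(
            f"Womersley number alpha={alpha:.1f} above the validated range (~20)",
            RuntimeWarning,
        )
    x, y, _ = grid.coords()
    if r_mm > max(x.max(), -x.min()) + 1e-9 or r_mm > max(y.max(), -y.min()) + 1e-9:
        raise ValueError("grid does not cover the lumen cross-section")

    rr = _radial(grid)
    inside = rr < r_mm
    times = np.arange(n_phases) * dt_ms * 1e-3
    vel = np.zeros((n_phases,) + grid.shape + (3,))
    for p, t in enumerate(times):
        vel[p, ..., 2] = womersley_velocity_profile(rr, t, harmonics, r_mm, fluid, f0)
        vel[p, ..., 2][~inside] = 0.0

    w0 = 2 * np.pi * f0
    q_t = np.array(
        [
            sum(
                (c * np.exp(1j * n * w0 * t)).real if n else c.real
                for n, c in enumerate(harmonics)
            )
            for t in times
        ]
    )
    tau_t = womersley_wall_shear(times, harmonics, r_mm, fluid, f0)

    def sampler(points_mm: np.ndarray, phase: int) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        r = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
        out = np.zeros((len(p), 3))
        out[:, 2] = womersley_velocity_profile(
            r, times[phase], harmonics, r_mm, fluid, f0
        )
        return out

    return VelocityField4D(
        origin=np.array(grid.origin),
        spacing=grid.spacing,
        velocity=vel,
        venc=venc,
        dt_ms=dt_ms,
        lumen_mask=inside,
        ground_truth={
            "q_ml_s": q_t,
            "wall_shear_pa": tau_t,
            "sampler": sampler,
            "radius_mm": r_mm,
            "alpha": float(alpha),
            "harmonics_ml_s": harmonics,
            "f0_hz": f0,
        },
    )


# ---------------------------------------------------------------------------
# PC-MRI acquisition model
# ---------------------------------------------------------------------------

def wrap_velocity(v: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into (-venc, venc] exactly as the phase encode does."""
    phase = np.pi * np.asarray(v, dtype=float) / venc
    wrapped = np.pi - np.mod(np.pi - phase, 2 * np.pi)
    return venc * wrapped / np.pi


def make_pc_series(
    field: VelocityField4D,
    venc: Optional[float] = None,
    target_snr: float = 120.0,
    seed: Optional[int] = None,
    lumen_signal: float = 100.0,
) -> tuple[MagnitudeSeries, VelocityField4D]:
    """Simulate a PC-MRI acquisition of an (exact) velocity field.

    Magnitude: constant signal A inside the lumen, A/10 outside, plus
    zero-mean Gaussian noise with sigma = A/target_snr, independent per
    cardiac phase. Velocity: each component encoded as phase pi*v/VENC, with
    Gaussian component noise sigma_v = (sqrt(2)/pi) * VENC / target_snr (the
    standard magnitude-to-velocity noise propagation), then wrapped into
    (-pi, pi] and decoded back as VENC*phase/pi. Deterministic under ``seed``.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    venc = field.venc if venc is None else float(venc)
    if venc <= 0:
        raise ValueError("venc must be positive")
    rng = np.random.default_rng(seed)

    A = float(lumen_signal)
    base = np.where(field.lumen_mask, A, A / 10.0)
    S = base[None] + rng.normal(0.0, A / target_snr, (field.n_phases,) + field.shape)
    S = np.clip(S, 0.0, None)

    sigma_v = (np.sqrt(2.0) / np.pi) * venc / target_snr
    noisy = field.velocity + rng.normal(0.0, sigma_v, field.velocity.shape)
    decoded = wrap_velocity(noisy, venc)

    mag = MagnitudeSeries(S=S, roi_vessel=field.lumen_mask.copy())
    out = VelocityField4D(
        origin=field.origin.copy(),
        spacing=field.spacing,
        velocity=decoded,
        venc=venc,
        dt_ms=field.dt_ms,
        lumen_mask=field.lumen_mask.copy(),
        ground_truth={"sigma_v_m_s": sigma_v, "lumen_signal": A, "target_snr": target_snr},
    )
    return mag, out
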