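"""Core containers for the near-wall hemodynamics pipeline.

Units convention, used everywhere in the package:

* lengths and grid spacing are in **millimetres**,
* velocities and VENC in **m/s**,
* time in **seconds** (cardiac phase spacing ``dt`` is given in ms where
  acquisitions are described, and converted on use),
* stresses in **Pa**, flow rates in **ml/s**.

Grids are cell-centred: voxel ``(i, j, k)`` has world coordinates
``origin + spacing * (i, j, k)``; axes are right-handed with array order
``(x, y, z)`` and the cardiac phase as the leading axis of velocity arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "FluidProperties",
    "FlowWaveform",
    "VelocityField4D",
    "MagnitudeSeries",
    "QualityMetrics",
    "BLOOD_ANALOGUE",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density rho [kg/m^3] and kinematic viscosity nu [m^2/s]."""

    density: float
    kinematic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("fluid properties must be strictly positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu [Pa s]."""
        return self.density * self.kinematic_viscosity


#: Glycerine/water blood analogue used throughout the synthetic study.
BLOOD_ANALOGUE = FluidProperties(density=1142.0, kinematic_viscosity=4.67e-6)


@dataclass
class FlowWaveform:
    """Volumetric flow rate over one cardiac period.

    ``times`` is a uniform grid spanning exactly one period T (the next sample
    after the last would be ``times[0] + T``); ``q`` is in ml/s.
    """

    times: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.q.shape:
            raise ValueError("times and q must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a waveform needs at least two samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def period(self) -> float:
        return self.dt * len(self.times)

    @property
    def f0(self) -> float:
        return 1.0 / self.period

    @property
    def q_bar(self) -> float:
        """Time average over the period (rectangle rule on the periodic grid)."""
        return float(np.mean(self.q))

    @property
    def systolic_index(self) -> int:
        return int(np.argmax(self.q))

    def harmonics(self, n_harmonics: int = 8) -> np.ndarray:
        """One-sided complex Fourier coefficients ``c[0..n]`` of Q(t).

        Q(t) = Re( sum_n c_n exp(i n w0 t) ) with c_0 real; computed by DFT on
        the uniform periodic grid.
        """
        n = len(self.q)
        spec = np.fft.rfft(self.q) / n
        c = np.zeros(min(n_harmonics, len(spec) - 1) + 1, dtype=complex)
        c[0] = spec[0].real
        # phase-reference the coefficients to absolute t=0, not times[0]
        c[1:] = 2.0 * spec[1 : len(c)] * np.exp(
            -1j * 2 * np.pi * np.arange(1, len(c)) * self.times[0] / self.period
        )
        return c


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity on a regular voxel grid.

    ``velocity`` has shape ``(n_phases, nx, ny, nz, 3)`` in m/s;
    ``lumen_mask`` has shape ``(nx, ny, nz)`` and defines the sampling domain
    of every statistic computed from the field.
    """

    origin: np.ndarray
    spacing: float
    velocity: np.ndarray
    venc: float
    dt_ms: float = 49.0
    lumen_mask: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (n_phases, nx, ny, nz, 3)")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.lumen_mask is None:
            self.lumen_mask = np.ones(self.velocity.shape[1:4], dtype=bool)
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        if self.lumen_mask.shape != self.velocity.shape[1:4]:
            raise ValueError("lumen_mask shape must match the grid")

    # -- grid bookkeeping ---------------------------------------------------
    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple:
        return self.velocity.shape[1:4]

    @property
    def period(self) -> float:
        """Cardiac period in seconds (phases are uniform, cycle periodic)."""
        return self.n_phases * self.dt_ms * 1e-3

    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.dt_ms * 1e-3

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of every voxel centre."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return self.origin + self.spacing * np.stack([ii, jj, kk], axis=-1)

    # -- sampling -----------------------------------------------------------
    def sample(self, points_mm: np.ndarray, phase: int, order: int = 1) -> np.ndarray:
        """Interpolate the velocity vector at world points (trilinear by default).

        Points outside the grid are extrapolated as zero.
        """
        idx = self.world_to_index(points_mm).T  # (3, N)
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.velocity[phase, ..., c], idx, order=order, mode="constant", cval=0.0
            )
        return out

    def sampler(self, order: int = 1) -> Callable[[np.ndarray, int], np.ndarray]:
        """A ``(points_mm, phase) -> (N, 3)`` closure over :meth:`sample`."""

        def _s(points_mm: np.ndarray, phase: int) -> np.ndarray:
            return self.sample(points_mm, phase, order=order)

        return _s

    def speed(self, phase: int) -> np.ndarray:
        return np.linalg.norm(self.velocity[phase], axis=-1)

    def mean_speed_in_mask(self, phase: int) -> float:
        return float(self.speed(phase)[self.lumen_mask].mean())

    def time_averaged_velocity(self) -> np.ndarray:
        """(nx, ny, nz, 3) time-averaged velocity field v-bar."""
        return self.velocity.mean(axis=0)

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            origin=self.origin.copy(),
            spacing=self.spacing,
            velocity=self.velocity.copy(),
            venc=self.venc,
            dt_ms=self.dt_ms,
            lumen_mask=self.lumen_mask.copy(),
            ground_truth=dict(self.ground_truth),
        )


@dataclass
class MagnitudeSeries:
    """PC magnitude images S(r, t*, k): shape (n_phases, nx, ny, nz), S >= 0.

    Slices are enumerated along ``slice_axis`` of the grid (default the third
    axis, the acquisition slab direction). ``roi_vessel`` marks the high-signal
    region of interest used by the SNR difference method.
    """

    S: np.ndarray
    roi_vessel: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.roi_vessel = np.asarray(self.roi_vessel, dtype=bool)
        if self.S.ndim != 4:
            raise ValueError("S must have shape (n_phases, nx, ny, nz)")
        if self.roi_vessel.shape != self.S.shape[1:]:
            raise ValueError("roi_vessel shape must match the grid")
        if np.any(self.S < 0):
            raise ValueError("magnitude signal must be non-negative")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must index a spatial axis (0, 1 or 2)")

    @property
    def n_phases(self) -> int:
        return self.S.shape[0]

    @property
    def n_slices(self) -> int:
        return self.S.shape[1 + self.slice_axis]


@dataclass
class QualityMetrics:
    """SNR (difference method) and VNR for one dataset."""

    snr: float
    vnr: float
    phase_pair: tuple
    per_slice_snr: np.ndarray
    mean_speed: float
    venc: float
    fallback_pair: bool = False

    def as_dict(self) -> dict:
        return {
            "snr": self.snr,
            "vnr": self.vnr,
            "phase_pair": list(self.phase_pair),
            "per_slice_snr": [float(x) for x in self.per_slice_snr],
            "mean_speed_m_s": self.mean_speed,
            "venc_m_s": self.venc,
            "fallback_pair": self.fallback_pair,
        }
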