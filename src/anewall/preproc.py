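"""Velocity-field cleaning: temporal unwrapping, outlier repair, lumen masking.

The acquisition encodes each velocity component as signal phase; true
velocities beyond VENC alias by 2*VENC. Around systole this shows up as
jumps larger than VENC between consecutive cardiac phases, which the
temporal unwrap removes by walking forward from a diastolic baseline.
Spurious near-wall vectors are then repaired with a normalized median test,
and the field is restricted to the co-registered lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np

from .core import VelocityField4D
from .geometry import RigidTransform, voxelize_surface
from .mesh import TriangleMesh

__all__ = ["OutlierReport", "unwrap_temporal", "median_filter_outliers", "mask_lumen"]


@dataclass
class OutlierReport:
    """Per-phase record of the normalized median test."""

    flagged: list  # per phase: (n_i, 3) voxel indices
    ratios: list  # per phase: (n_i,) max component residual ratio
    replacements: list  # per phase: (n_i, 3) replacement vectors [m/s]
    skipped: np.ndarray = dfield(default_factory=lambda: np.zeros((0, 3), int))

    @property
    def n_flagged(self) -> int:
        return int(sum(len(f) for f in self.flagged))


def unwrap_temporal(field: VelocityField4D, venc: Optional[float] = None) -> VelocityField4D:
    """Undo temporal velocity aliasing by 2*VENC jump detection.

    Walking forward in time from the diastolic baseline (the cardiac phase
    with minimum spatial-mean speed inside the lumen), a step between
    consecutive phases exceeding +VENC subtracts 2*VENC from all subsequent
    samples of that voxel/component, and a step below -VENC adds 2*VENC.
    Output values may legitimately exceed VENC. Double wraps that do not
    step through intermediate phases remain unresolved and are flagged in
    the returned field's ``unwrap_unresolved`` attribute.
    """
    venc = field.venc if venc is None else float(venc)
    if venc <= 0:
        raise ValueError("venc must be positive")
    if field.n_phases < 2:
        raise ValueError("unwrapping needs at least two cardiac phases")

    # Diastolic baseline: minimum spatial-mean speed. Aliased voxels fake low
    # speeds at systole, so voxels whose temporal step to a neighbouring phase
    # exceeds VENC (wrap suspects) are excluded from the statistic.
    vm = field.velocity[:, field.lumen_mask]  # (T, Nvox, 3)
    T = field.n_phases
    mean_speed = np.linalg.norm(vm, axis=-1).mean(axis=1)
    # wrap events (steps beyond VENC) cluster around systole; diastole is the
    # phase cyclically farthest from any of them (plain minimum mean speed
    # when nothing wraps)
    step_hi = np.abs(np.diff(vm, axis=0, append=vm[:1])).max(axis=-1) > venc
    events = step_hi.sum(axis=1)  # events[p]: wraps on the step p -> p+1
    active = np.flatnonzero(events > max(1, int(2e-4 * vm.shape[1])) - 1)
    if len(active) == 0:
        baseline = int(np.argmin(mean_speed))
    else:
        # distance from phase p to the nearest active step boundary
        dists = np.min(
            np.minimum(
                np.abs(np.arange(T)[:, None] - active[None, :]),
                T - np.abs(np.arange(T)[:, None] - active[None, :]),
            ),
            axis=1,
        )
        candidates = np.flatnonzero(dists == dists.max())
        baseline = int(candidates[np.argmin(mean_speed[candidates])])
    order = [(baseline + i) % field.n_phases for i in range(field.n_phases)]

    v = field.velocity
    out = v.copy()
    corr = np.zeros(v.shape[1:], dtype=float)  # running correction per voxel/component
    for i in range(1, field.n_phases):
        prev, cur = order[i - 1], order[i]
        d = v[cur] - v[prev]  # raw step between consecutive phases
        corr = corr - 2 * venc * (d > venc) + 2 * venc * (d < -venc)
        out[cur] = v[cur] + corr

    # cyclic consistency: one full cycle must have zero net wrap count;
    # a nonzero winding means a wrap was crossed without detectable steps
    # (e.g. a double wrap jumped in a single phase step) and is unresolved
    d_close = v[order[0]] - v[order[-1]]
    winding = corr / (2 * venc) + (d_close < -venc) - (d_close > venc)
    unresolved = np.any(winding != 0, axis=-1)

    res = VelocityField4D(
        origin=field.origin.copy(),
        spacing=field.spacing,
        velocity=out,
        venc=venc,
        dt_ms=field.dt_ms,
        lumen_mask=field.lumen_mask.copy(),
        ground_truth=dict(field.ground_truth),
    )
    res.unwrap_unresolved = unresolved
    res.unwrap_baseline = baseline
    return res


_INPLANE_OFFSETS = {
    0: [(0, dy, dz) for dy in (-1, 0, 1) for dz in (-1, 0, 1) if (dy, dz) != (0, 0)],
    1: [(dx, 0, dz) for dx in (-1, 0, 1) for dz in (-1, 0, 1) if (dx, dz) != (0, 0)],
    2: [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)],
}


def _dominant_axis(field: VelocityField4D) -> int:
    m = field.lumen_mask
    comp_means = np.abs(field.velocity[:, m].mean(axis=(0, 1)))
    return int(np.argmax(comp_means))


def median_filter_outliers(
    field: VelocityField4D,
    n_neighbors: int = 8,
    threshold: float = 1.0,
    epsilon: Optional[float] = None,
    plane_axis: Optional[int] = None,
) -> tuple[VelocityField4D, OutlierReport]:
    """Normalized median test on the 8 in-plane lumen neighbours.

    For each lumen voxel and phase, with m the component-wise median of the
    in-plane neighbours and r_med the median neighbour residual |v_j - m|,
    the voxel is flagged when max over components of
    |v_i - m| / (r_med + epsilon) exceeds the detection threshold, and
    replaced by m. Voxels with fewer than 3 valid neighbours are left
    untouched and listed separately. ``epsilon`` is the acquisition noise
    floor (default 0.05 * VENC); the slice plane is orthogonal to the
    dominant flow axis unless ``plane_axis`` overrides it.
    """
    if n_neighbors != 8:
        raise ValueError("the normalized median test is defined on 8 in-plane neighbours")
    eps = 0.05 * field.venc if epsilon is None else float(epsilon)
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    axis = _dominant_axis(field) if plane_axis is None else int(plane_axis)
    offsets = _INPLANE_OFFSETS[axis]

    mask = field.lumen_mask
    nx, ny, nz = mask.shape
    out = field.velocity.copy()
    flagged_all, ratios_all, repl_all = [], [], []

    # neighbour stacks with NaN outside the lumen / grid
    def shifted(arr: np.ndarray, off) -> np.ndarray:
        pad = np.full_like(arr, np.nan)
        sl_src = [slice(None)] * 3
        sl_dst = [slice(None)] * 3
        for a, o in enumerate(off):
            if o == 1:
                sl_src[a] = slice(1, None)
                sl_dst[a] = slice(None, -1)
            elif o == -1:
                sl_src[a] = slice(None, -1)
                sl_dst[a] = slice(1, None)
        pad[tuple(sl_dst)] = arr[tuple(sl_src)]
        return pad

    nanmask = np.where(mask, 1.0, np.nan)
    n_valid = np.zeros(mask.shape)
    for off in offsets:
        n_valid += ~np.isnan(shifted(nanmask, off))
    few = mask & (n_valid < 3)
    enough = mask & (n_valid >= 3)

    for p in range(field.n_phases):
        v = np.where(mask[..., None], field.velocity[p], np.nan)
        stack = np.stack([shifted(v, off) for off in offsets])  # (8, nx, ny, nz, 3)
        with np.errstate(invalid="ignore"):
            m = np.nanmedian(stack, axis=0)
            r = np.abs(stack - m[None])
            r_med = np.nanmedian(r, axis=0)
            ratio = np.abs(field.velocity[p] - m) / (r_med + eps)
        ratio_max = np.where(enough[..., None], ratio, 0.0).max(axis=-1)
        flag = enough & (ratio_max > threshold)
        ij = np.argwhere(flag)
        flagged_all.append(ij)
        ratios_all.append(ratio_max[flag])
        repl = m[flag]
        repl_all.append(repl)
        out[p][flag] = repl

    report = OutlierReport(
        flagged=flagged_all, ratios=ratios_all, replacements=repl_all,
        skipped=np.argwhere(few),
    )
    res = VelocityField4D(
        origin=field.origin.copy(),
        spacing=field.spacing,
        velocity=out,
        venc=field.venc,
        dt_ms=field.dt_ms,
        lumen_mask=mask.copy(),
        ground_truth=dict(field.ground_truth),
    )
    return res, report


def mask_lumen(
    field: VelocityField4D,
    surface: TriangleMesh,
    transform: Optional[RigidTransform] = None,
) -> VelocityField4D:
    """Restrict the field to voxels whose centre lies inside the surface.

    ``transform`` maps surface coordinates into image coordinates (identity
    by default). Velocities outside the lumen are zeroed and excluded from
    all downstream statistics. The surface must be watertight.
    """
    surf = surface
    if transform is not None:
        surf = TriangleMesh(transform.apply(surface.vertices), surface.faces.copy())
    mask = voxelize_surface(surf, field.origin, field.spacing, field.shape)
    if not mask.any():
        raise ValueError("transformed surface does not overlap the velocity grid")
    vel = np.where(mask[None, ..., None], field.velocity, 0.0)
    return VelocityField4D(
        origin=field.origin.copy(),
        spacing=field.spacing,
        velocity=vel,
        venc=field.venc,
        dt_ms=field.dt_ms,
        lumen_mask=mask,
        ground_truth=dict(field.ground_truth),
    )
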