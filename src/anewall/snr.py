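"""PC-MRI quality metrics: SNR by the two-phase difference method, and VNR.

Two consecutive cardiac phases with near-identical flow contain the same
signal but independent noise, so their sum estimates 2x the signal and their
difference estimates sqrt(2)x the noise:

    SNR = mean_k [ mean_ROI(S_i + S_{i+1}) / (sqrt(2) * std_ROI(S_i - S_{i+1})) ]

averaged over slices k. The velocity-to-noise ratio scales SNR by how much
of the encoding range the flow actually uses:

    VNR = (pi / sqrt(2)) * (mean |v-bar| / VENC) * SNR
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .core import MagnitudeSeries, QualityMetrics, VelocityField4D

__all__ = ["select_phase_pair", "snr_difference", "vnr", "quality_metrics"]


def select_phase_pair(
    field: VelocityField4D,
    series: Optional[MagnitudeSeries] = None,
    max_rel_diff: float = 0.01,
) -> tuple[int, int, bool]:
    """Pick consecutive cardiac phases (i, i+1) suited to the difference method.

    Candidates are consecutive pairs whose lumen-mean speeds differ by at
    most ``max_rel_diff`` relative (these cluster around diastole); among
    them the pair with the highest difference-method SNR wins (lowest index
    on ties, or when no magnitude series is given). If no pair qualifies,
    the minimum-difference pair is returned with the fallback flag set and a
    warning.
    """
    if field.n_phases < 2:
        raise ValueError("need at least two cardiac phases")
    speeds = np.array([field.mean_speed_in_mask(p) for p in range(field.n_phases)])
    denom = np.maximum(np.minimum(speeds[:-1], speeds[1:]), 1e-30)
    rel = np.abs(np.diff(speeds)) / denom
    qualifying = np.flatnonzero(rel <= max_rel_diff)
    if len(qualifying) == 0:
        i = int(np.argmin(rel))
        warnings.warn(
            "no consecutive phase pair within the mean-speed tolerance; "
            f"falling back to the minimum-difference pair ({i}, {i + 1})",
            RuntimeWarning,
        )
        return i, i + 1, True
    if series is None:
        i = int(qualifying[0])
        return i, i + 1, False
    snrs = [snr_difference(series, (int(i), int(i) + 1)) for i in qualifying]
    best = int(qualifying[int(np.argmax(snrs))])
    return best, best + 1, False


def snr_difference(
    series: MagnitudeSeries,
    pair: tuple[int, int],
    roi: Optional[np.ndarray] = None,
) -> float:
    """Difference-method SNR averaged over slices (see module docstring)."""
    i, j = pair
    roi = series.roi_vessel if roi is None else np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    si = np.moveaxis(series.S[i], series.slice_axis, 0)
    sj = np.moveaxis(series.S[j], series.slice_axis, 0)
    rk = np.moveaxis(roi, series.slice_axis, 0)
    vals = []
    for k in range(si.shape[0]):
        m = rk[k]
        if not m.any():
            continue
        num = np.mean(si[k][m] + sj[k][m])
        den = np.std(si[k][m] - sj[k][m])
        if den == 0:
            raise ZeroDivisionError(
                f"zero difference stddev on slice {k}: images are identical/noiseless"
            )
        vals.append(num / (np.sqrt(2.0) * den))
    if not vals:
        raise ValueError("ROI is empty on every slice")
    return float(np.mean(vals))


def vnr(snr: float, mean_speed: float, venc: float) -> float:
    """VNR = (pi/sqrt(2)) * (mean_speed / VENC) * SNR.

    ``mean_speed`` is the spatial mean of |v-bar| (time-averaged velocity)
    over the fluid volume, in m/s.
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    if mean_speed < 0 or snr < 0:
        raise ValueError("snr and mean_speed must be non-negative")
    return float(np.pi / np.sqrt(2.0) * (mean_speed / venc) * snr)


def quality_metrics(field: VelocityField4D, series: MagnitudeSeries) -> QualityMetrics:
    """End-to-end SNR + VNR for one dataset."""
    i, j, fallback = select_phase_pair(field, series)
    snr_val = snr_difference(series, (i, j))
    vbar = field.time_averaged_velocity()
    mean_speed = float(np.linalg.norm(vbar, axis=-1)[field.lumen_mask].mean())
    per_slice = []
    si = np.moveaxis(series.S[i], series.slice_axis, 0)
    sj = np.moveaxis(series.S[j], series.slice_axis, 0)
    rk = np.moveaxis(series.roi_vessel, series.slice_axis, 0)
    for k in range(si.shape[0]):
        m = rk[k]
        if not m.any():
            continue
        den = np.std(si[k][m] - sj[k][m])
        per_slice.append(np.mean(si[k][m] + sj[k][m]) / (np.sqrt(2.0) * den))
    return QualityMetrics(
        snr=snr_val,
        vnr=vnr(snr_val, mean_speed, field.venc),
        phase_pair=(i, j),
        per_slice_snr=np.array(per_slice),
        mean_speed=mean_speed,
        venc=field.venc,
        fallback_pair=fallback,
    )
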