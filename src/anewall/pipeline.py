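"""End-to-end orchestration of the near-wall hemodynamics chain.

Stage order mirrors the measurement workflow: temporal unwrap -> outlier
repair -> rigid co-registration -> lumen masking -> orthogonal-plane flow
rates (+ reference-waveform comparison, Reynolds/Womersley numbers) -> sac
isolation and morphometrics -> WSS / TAWSS / OSI -> SNR / VNR. Inputs come
either from files (NIfTI velocities, STL/PLY surface, CSV centerline and
reference waveform) or from the built-in synthetic cases.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import flow as flow_mod
from . import geometry as geo
from . import io as io_mod
from . import preproc, snr, synthetic, wss
from .core import BLOOD_ANALOGUE, FlowWaveform, FluidProperties, MagnitudeSeries, VelocityField4D
from .mesh import TriangleMesh

__all__ = ["CaseConfig", "ConfigError", "StageError", "run_case", "make_synthetic_case"]


class ConfigError(ValueError):
    """Invalid or inconsistent case configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CaseConfig:
    """Declarative description of one case.

    Either ``synthetic`` names a built-in phantom case ("tube" or "sac"), or
    the velocity/surface/centerline paths point at acquired data. Defaults
    mirror the emulated acquisition: 0.5 mm voxels, 21 phases at 49 ms,
    VENC 1.1 m/s, glycerine/water blood analogue.
    """

    synthetic: Optional[str] = None
    velocity_paths: Optional[list] = None
    velocity_dialect: str = "velocity"
    surface_path: Optional[str] = None
    centerline_path: Optional[str] = None
    reference_waveform_path: Optional[str] = None
    venc: float = 1.1
    dt_ms: float = 49.0
    n_phases: int = 21
    voxel_mm: float = 0.5
    q_bar_ml_s: float = 4.38
    tube_radius_mm: float = 1.675
    sac_radius_mm: float = 4.0
    neck_radius_mm: float = 3.0
    tube_length_mm: float = 20.0
    target_snr: float = 120.0
    fluid: FluidProperties = dfield(default_factory=lambda: BLOOD_ANALOGUE)
    plane_spacing_mm: float = 1.0
    seed: int = 0
    stages: dict = dfield(default_factory=dict)  # stage toggles, default all on

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        if "fluid" in d and isinstance(d["fluid"], dict):
            d["fluid"] = FluidProperties(**d["fluid"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CaseConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.venc <= 0:
            raise ConfigError("VENC must be positive")
        if self.fluid.density <= 0 or self.fluid.kinematic_viscosity <= 0:
            raise ConfigError("fluid properties must be positive")
        if self.synthetic is None:
            for name in ("velocity_paths", "surface_path"):
                val = getattr(self, name)
                if val is None:
                    raise ConfigError(f"non-synthetic case requires {name}")
            for p in list(self.velocity_paths) + [self.surface_path]:
                if not Path(p).exists():
                    raise ConfigError(f"missing input file: {p}")
        elif self.synthetic not in ("tube", "sac"):
            raise ConfigError("synthetic case must be 'tube' or 'sac'")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def make_synthetic_case(cfg: CaseConfig):
    """Build (field, magnitude series, surface, centerline, reference waveform).

    The tube case is a straight vessel carrying the pulsatile Womersley flow
    of the built-in waveform; the sac case attaches a spherical aneurysm.
    The acquisition model adds noise and wrapping at the configured SNR.
    """
    wf = synthetic.make_ica_waveform(cfg.q_bar_ml_s, n_phases=cfg.n_phases, dt_ms=cfg.dt_ms)
    if cfg.synthetic == "tube":
        surface, cl = synthetic.make_tube_phantom(cfg.tube_radius_mm, cfg.tube_length_mm)
    else:
        surface, cl = synthetic.make_sphere_on_tube(
            cfg.tube_radius_mm, cfg.sac_radius_mm, cfg.neck_radius_mm, cfg.tube_length_mm
        )
    margin = 2.0 if cfg.synthetic == "tube" else cfg.sac_radius_mm * 2 + 2.0
    grid = synthetic.GridSpec.for_tube(
        cfg.tube_radius_mm, cfg.tube_length_mm, spacing=cfg.voxel_mm, margin=margin
    )
    truth = synthetic.sample_womersley(
        grid, wf, cfg.tube_radius_mm, cfg.fluid, venc=cfg.venc
    )
    mag, acq = synthetic.make_pc_series(
        truth, venc=cfg.venc, target_snr=cfg.target_snr, seed=cfg.seed
    )
    return truth, acq, mag, surface, cl, wf


def run_case(
    config: Union[CaseConfig, dict, str, Path],
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Execute the full chain and return (and optionally write) the report.

    The report is deterministic under the config seed; stage wall times are
    logged separately (``timings`` is not part of the persisted report).
    """
    if isinstance(config, (str, Path)):
        config = CaseConfig.from_file(config)
    elif isinstance(config, dict):
        config = CaseConfig.from_dict(config)
    config.validate()
    report: dict = {"case": config.synthetic or "files", "seed": config.seed}
    timings: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    if out_dir is not None:
                        io_mod.write_json(report, Path(out_dir) / "report_partial.json")
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # ---- inputs ----------------------------------------------------------
    with stage("inputs"):
        if config.synthetic is not None:
            truth, field, mag, surface, cl, ref_wf = make_synthetic_case(config)
        else:
            field = io_mod.read_velocity_nifti(
                config.velocity_paths, config.venc, config.dt_ms,
                dialect=config.velocity_dialect,
            )
            surface = (
                io_mod.read_stl(config.surface_path)
                if str(config.surface_path).endswith(".stl")
                else io_mod.read_ply(config.surface_path)
            )
            cl = (
                io_mod.read_centerline_csv(config.centerline_path)
                if config.centerline_path
                else None
            )
            ref_wf = (
                io_mod.read_waveform_csv(config.reference_waveform_path)
                if config.reference_waveform_path
                else None
            )
            mag = None
            truth = None

    # ---- preprocessing ---------------------------------------------------
    with stage("unwrap"):
        if config.enabled("unwrap"):
            field = preproc.unwrap_temporal(field)
            report["unwrap"] = {
                "baseline_phase": int(field.unwrap_baseline),
                "unresolved_voxels": int(field.unwrap_unresolved.sum()),
            }

    with stage("register"):
        transform = geo.RigidTransform.identity()
        if config.enabled("register"):
            transform, info = geo.register_rigid(surface, field)
            report["registration"] = {
                "euler_deg": transform.euler_deg().tolist(),
                "translation_mm": transform.translation.tolist(),
                "converged": info["converged"],
            }

    with stage("mask"):
        field = preproc.mask_lumen(field, surface, transform)
        report["lumen_voxels"] = int(field.lumen_mask.sum())

    with stage("outliers"):
        if config.enabled("outliers"):
            field, rep = preproc.median_filter_outliers(field)
            report["outliers"] = {
                "flagged": rep.n_flagged,
                "skipped_few_neighbors": int(len(rep.skipped)),
            }

    # ---- flow rates ------------------------------------------------------
    with stage("flow"):
        if cl is None:
            raise ValueError("a centerline is required for flow quantification")
        planes = geo.orthogonal_planes(cl, config.plane_spacing_mm, end_margin=1.0)
        moved_surface = TriangleMesh(transform.apply(surface.vertices), surface.faces.copy())
        q_series = []
        for pl in planes:
            try:
                q_series.append(flow_mod.plane_flow_rate(field, pl, surface=moved_surface))
            except ValueError:
                continue  # plane misses the lumen (e.g. beyond a clipped end)
        stats = flow_mod.interplane_stats(q_series)
        mean_wf = FlowWaveform(times=field.times(), q=stats.mean)
        dimless = flow_mod.DimensionlessNumbers(
            re_m=flow_mod.reynolds_number(
                mean_wf.q_bar, float(cl.diameters[0]), config.fluid.kinematic_viscosity
            ),
            alpha=flow_mod.womersley_number(
                float(cl.diameters[0]), mean_wf.f0, config.fluid.kinematic_viscosity
            ),
            omega0=2 * np.pi * mean_wf.f0,
            f0=mean_wf.f0,
            d=float(cl.diameters[0]),
        )
        report["flow"] = {
            "n_planes": len(q_series),
            "q_bar_ml_s": mean_wf.q_bar,
            "systolic_index": stats.systolic_index,
            "interplane_std_over_mean": float(
                np.mean(stats.std[stats.mean != 0] / np.abs(stats.mean[stats.mean != 0]))
            ),
            "re_m": dimless.re_m,
            "alpha": dimless.alpha,
        }
        if ref_wf is not None:
            cmp = flow_mod.compare_waveforms(mean_wf, ref_wf)
            report["flow"]["vs_reference"] = {
                "time_averaged_difference_pct": cmp.time_averaged_difference,
                "systolic_difference_pct": cmp.systolic_difference,
            }

    # ---- sac geometry ----------------------------------------------------
    sac_iso = None
    with stage("sac"):
        if config.enabled("sac"):
            sac_iso = geo.isolate_sac(surface, cl)
            if sac_iso.status == "empty":
                report["sac"] = {"status": "empty"}
                sac_iso = None
            else:
                plane = geo.fit_neck_plane(sac_iso.neck_loop)
                morpho = geo.sac_morphometrics(sac_iso.sac, plane, sac_iso.neck_loop, cl)
                report["sac"] = {"status": "ok", **morpho.as_dict(),
                                 "neck_plane_residual_mm": plane.residual}

    # ---- wall shear ------------------------------------------------------
    with stage("wss"):
        if config.enabled("wss") and sac_iso is not None:
            record = wss.wss_field(
                field, sac_iso.sac, config.fluid.dynamic_viscosity,
                systolic_index=stats.systolic_index,
            )
            _, tmag = wss.tawss(record)
            osi_vals = wss.osi(record)
            syst = stats.systolic_index
            ok = record.valid
            defined = ok & ~np.isnan(osi_vals)
            report["wss"] = {
                "systolic_max_pa": float(record.magnitudes()[syst, ok].max()),
                "systolic_mean_pa": float(record.magnitudes()[syst, ok].mean()),
                "tawss_mean_pa": float(tmag[ok].mean()),
                "osi_max": float(osi_vals[defined].max()) if defined.any() else None,
                "flagged_vertices": int((~record.valid).sum()),
            }
            if out_dir is not None:
                import pandas as pd

                Path(out_dir).mkdir(parents=True, exist_ok=True)
                pd.DataFrame(
                    {
                        "x_mm": record.basis.points[:, 0],
                        "y_mm": record.basis.points[:, 1],
                        "z_mm": record.basis.points[:, 2],
                        "tawss_pa": tmag,
                        "osi": osi_vals,
                        "valid": record.valid,
                    }
                ).to_csv(Path(out_dir) / "wall_fields.csv", index=False)

    # ---- quality metrics -------------------------------------------------
    with stage("quality"):
        if config.enabled("quality") and mag is not None:
            mag = MagnitudeSeries(S=mag.S, roi_vessel=field.lumen_mask)
            qm = snr.quality_metrics(field, mag)
            report["quality"] = qm.as_dict()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_json(report, out / "report.json")
        io_mod.write_waveform_csv(mean_wf, out / "flow_interplane_mean.csv")
        if ref_wf is not None:
            io_mod.write_waveform_csv(ref_wf, out / "flow_reference.csv")
        io_mod.write_json({"timings_s": timings}, out / "timings.json")
    return report
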