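"""End-to-end orchestration: ingest -> kinematics -> pressure -> forces
-> efficiency, with provenance and QC metrics.

``analyze`` is the library entry point (in-memory objects in, an
:class:`AnalysisReport` out); ``run`` wraps it with config-file I/O.
Interior frames only carry results (the first and last velocity frames
lack the centered time stencil the pressure stage needs). Stage failures
are re-raised as :class:`~pullpush.errors.StageError` with the stage
name and frame index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError, DataError, PullPushError, StageError
from .forces import (
    CycleForceSummary,
    ForceDecomposition,
    decompose_forces,
    sample_surface_pressure,
    summarize_cycle,
)
from .efficiency import EfficiencyReport, lateral_power, partition_efficiencies
from .grids import AnalysisConfig, MaskSequence, VelocitySequence
from .io import read_config, read_mask_sequence, read_velocity_sequence, write_report
from .kinematics import (
    body_surface_vorticity,
    extract_contour,
    resample_contour,
    surface_kinematics,
    swim_frame,
    vorticity_field,
)
from .pressure import pressure_sequence

__all__ = ["AnalysisReport", "analyze", "run"]


@dataclass
class AnalysisReport:
    provenance: dict
    swim: dict
    cycle_summary: dict
    efficiency: dict
    frames: list[dict]
    qc: dict
    decompositions: list[ForceDecomposition] = field(default_factory=list, repr=False)

    def to_report_dict(self) -> dict:
        return {
            "schema_version": 1,
            "provenance": self.provenance,
            "swim": self.swim,
            "cycle_summary": self.cycle_summary,
            "efficiency": self.efficiency,
            "qc": self.qc,
            "frames": self.frames,
        }


def _config_provenance(config: AnalysisConfig) -> dict:
    cfg = asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.rng_seed,
        "pullpush_version": __version__,
        "numpy_version": np.__version__,
        "viscous_surface_forces": "not computed (pressure forces only)",
    }


def analyze(
    velocity: VelocitySequence,
    masks: MaskSequence,
    config: AnalysisConfig | None = None,
    axis=None,
) -> AnalysisReport:
    """Run the full measurement-to-inference chain.

    ``axis`` supplies the symmetry axis (point, direction) in
    axisymmetric mode.
    """
    config = config or AnalysisConfig()
    velocity.require_frames(3)
    if len(masks) != len(velocity):
        raise DataError("mask and velocity sequences differ in length")
    grid = velocity.grid

    # --- contours (first pass anchored at max-x, re-anchored once the
    # swimming direction is known)
    polylines = []
    for k, m in enumerate(masks):
        try:
            polylines.append(extract_contour(m, grid))
        except PullPushError as e:
            raise StageError("kinematics/extract_contour", k, e) from e
    times = velocity.times
    contours0 = [
        resample_contour(pl, n=config.n_control_points, t=t)
        for pl, t in zip(polylines, times)
    ]
    try:
        swim = swim_frame(
            contours0,
            mode="fixed" if config.swim_axis_mode == "fixed-vector" else "auto",
            fixed_vector=config.fixed_axis,
            min_displacement=0.1 * grid.dx,
        )
    except PullPushError as e:
        raise StageError("kinematics/swim_frame", None, e) from e
    contours = [
        resample_contour(pl, n=config.n_control_points, s_hat=swim.s_hat, t=t)
        for pl, t in zip(polylines, times)
    ]

    # --- pressure on interior frames
    try:
        pressures = pressure_sequence(velocity, masks, config.fluid, config)
    except PullPushError as e:
        raise StageError("pressure", None, e) from e

    # --- per-frame forces, kinematics and lateral power
    decomps: list[ForceDecomposition] = []
    lat = {"all": [], "pull": [], "push": []}
    frame_rows = []
    qc_interp = []
    qc_unresolved = []
    bsv_sign_match = []
    for k in range(1, len(velocity) - 1):
        pf = pressures[k - 1]
        try:
            kin = surface_kinematics(contours[k - 1], contours[k], contours[k + 1], velocity.dt)
            vort = vorticity_field(velocity[k])
            kin.bsv, kin.bsv_valid = body_surface_vorticity(contours[k], vort)
            sample = sample_surface_pressure(pf, contours[k], offset=config.surface_sample_offset)
            dec = decompose_forces(
                sample, contours[k], swim,
                mode=config.geometry_mode, axis=axis, dead_band=config.dead_band,
            )
            for name in lat:
                lat[name].append(
                    lateral_power(
                        sample, kin, contours[k], swim, subset=name,
                        mode=config.geometry_mode, axis=axis, dead_band=config.dead_band,
                    )
                )
        except PullPushError as e:
            raise StageError(config.geometry_mode + " forces", k, e) from e
        decomps.append(dec)
        fluid_nodes = (~masks[k]).sum()
        qc_interp.append(float((pf.interpolated & ~masks[k]).sum() / max(fluid_nodes, 1)))
        qc_unresolved.append(float((~sample.resolved).mean()))
        ok = kin.bsv_valid
        if ok.any():
            bsv_sign_match.append(
                float(np.mean(np.sign(kin.bsv[ok]) == np.sign(kin.bsr_point[ok])))
            )
        frame_rows.append(
            {
                "t": float(velocity[k].t),
                "F_fpull": dec.F_fpull,
                "F_rpull": dec.F_rpull,
                "F_fpush": dec.F_fpush,
                "F_rpush": dec.F_rpush,
                "net_thrust": dec.net_thrust,
                "gross_thrust": dec.gross_thrust,
                "gross_drag": dec.gross_drag,
                "P_lat": lat["all"][-1],
                "P_lat_pull": lat["pull"][-1],
                "P_lat_push": lat["push"][-1],
            }
        )

    summary = summarize_cycle(decomps, cycle_bounds=config.cycle_bounds)
    t_mid = np.array([d.t for d in decomps])
    if config.cycle_bounds is not None:
        sel = (t_mid >= config.cycle_bounds[0] - 1e-12) & (t_mid <= config.cycle_bounds[1] + 1e-12)
    else:
        sel = np.ones(len(t_mid), dtype=bool)
    lat_w = {k: np.asarray(v)[sel] for k, v in lat.items()}
    report = partition_efficiencies(summary, lat_w, t_mid[sel], swim)

    # divergence residual on the middle frame (QC only)
    mid = velocity[len(velocity) // 2]
    du = np.gradient(mid.u, grid.dy, grid.dx)[1]
    dv = np.gradient(mid.v, grid.dy, grid.dx)[0]
    div = np.abs(du + dv)[mid.valid]
    speed = mid.speed()[mid.valid]
    div_resid = float(np.nanmedian(div) * grid.dx / max(np.nanmedian(speed), 1e-30))

    return AnalysisReport(
        provenance=_config_provenance(config),
        swim={
            "s_hat": list(swim.s_hat),
            "j_hat": list(swim.j_hat),
            "U": swim.U,
            "U_bl": swim.U_bl,
            "body_length": swim.body_length,
        },
        cycle_summary=asdict(summary),
        efficiency=report.to_dict(),
        frames=frame_rows,
        qc={
            "interpolated_pressure_fraction": float(np.mean(qc_interp)),
            "unresolved_surface_fraction": float(np.mean(qc_unresolved)),
            "divergence_residual": div_resid,
            "bsv_bsr_sign_match": float(np.mean(bsv_sign_match)) if bsv_sign_match else None,
        },
        decompositions=decomps,
    )


def run(config_path, out_dir=None) -> AnalysisReport:
    """Load inputs named in a TOML config, analyze, optionally write the
    report. The ``[inputs]`` section must give ``velocity`` and ``masks``
    paths (relative to the config file)."""
    config_path = Path(config_path)
    config, extra = read_config(config_path)
    inputs = extra.get("inputs")
    if not inputs or "velocity" not in inputs or "masks" not in inputs:
        raise ConfigError("config needs an [inputs] section with velocity and masks paths")
    base = config_path.parent
    velocity = read_velocity_sequence(
        base / inputs["velocity"],
        dialect=inputs.get("dialect", "auto"),
        scale=float(inputs.get("scale", 1.0)),
    )
    masks = read_mask_sequence(base / inputs["masks"], velocity.grid)
    axis = None
    if "axis" in inputs:
        ax = inputs["axis"]
        axis = (tuple(ax["point"]), tuple(ax["direction"]))
    report = analyze(velocity, masks, config, axis=axis)
    if out_dir is not None:
        write_report(report.to_report_dict(), out_dir)
    return report
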