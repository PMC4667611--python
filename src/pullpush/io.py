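"""Readers and writers for velocity sequences, masks, configuration and
analysis reports.

Two velocity dialects are supported:

``per-frame-table``
    A directory holding one delimited text table per frame with columns
    ``x, y, u, v[, valid]`` on a complete regular lattice, plus a
    ``meta.json`` carrying grid spacing, origin, times and units. This is
    the working format; it matches common velocimetry exports.

``gridded-container``
    A single netCDF file (classic format, via the xarray/scipy backend)
    with variables ``u(time, y, x)``, ``v`` and ``valid``. This is the
    archival format.

Floats are written with 17 significant digits so a write -> read round
trip is bit-identical.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigError, DataError
from .grids import (
    AnalysisConfig,
    FluidProperties,
    Grid2D,
    MaskSequence,
    VelocityFrame,
    VelocitySequence,
)

__all__ = [
    "read_velocity_sequence",
    "write_velocity_sequence",
    "read_mask_sequence",
    "write_mask_sequence",
    "read_config",
    "write_report",
    "read_report",
]

_FMT = "%.17g"
#: lattice-regularity tolerance, as a fraction of the node spacing
LATTICE_RTOL = 1e-6


# ---------------------------------------------------------------------------
# velocity sequences


def _grid_from_xy(xs: np.ndarray, ys: np.ndarray) -> Grid2D:
    """Infer a Grid2D from sorted unique node coordinates; reject
    non-uniform lattices."""
    for name, c in (("x", xs), ("y", ys)):
        if len(c) < 3:
            raise DataError(f"irregular grid: fewer than 3 unique {name} values")
        d = np.diff(c)
        if np.any(np.abs(d - d[0]) > LATTICE_RTOL * abs(d[0])):
            raise DataError(f"irregular grid: non-uniform {name} spacing")
    return Grid2D(
        nx=len(xs), ny=len(ys), dx=float(np.diff(xs)[0]), dy=float(np.diff(ys)[0]),
        origin=(float(xs[0]), float(ys[0])),
    )


def _frame_from_table(path: Path, t: float, scale: float = 1.0) -> VelocityFrame:
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "," if "," in header else r"\s+"
        # round_trip parsing: the writer emits 17 significant digits so a
        # write -> read cycle is bit-identical
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except OSError as e:
        raise DataError(f"cannot read velocity table {path}: {e}") from e
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("x", "y", "u", "v"):
        if need not in cols:
            raise DataError(f"{path}: missing column {need!r}")
    x = df[cols["x"]].to_numpy(float) * scale
    y = df[cols["y"]].to_numpy(float) * scale
    xs = np.unique(x)
    ys = np.unique(y)
    grid = _grid_from_xy(xs, ys)
    if len(df) != grid.nx * grid.ny:
        raise DataError(
            f"irregular grid: {path} has {len(df)} rows, lattice needs {grid.nx * grid.ny}"
        )
    j = np.rint((x - grid.origin[0]) / grid.dx).astype(int)
    i = np.rint((y - grid.origin[1]) / grid.dy).astype(int)
    if len(np.unique(i * grid.nx + j)) != grid.nx * grid.ny:
        raise DataError(f"irregular grid: duplicate or missing lattice nodes in {path}")
    u = np.full(grid.shape, np.nan)
    v = np.full(grid.shape, np.nan)
    u[i, j] = df[cols["u"]].to_numpy(float) * scale
    v[i, j] = df[cols["v"]].to_numpy(float) * scale
    if "valid" in cols:
        valid = np.ones(grid.shape, dtype=bool)
        valid[i, j] = df[cols["valid"]].to_numpy(float) != 0
    else:
        valid = None
    return VelocityFrame(grid, t, u, v, valid)


def read_velocity_sequence(path, dialect: str = "auto", scale: float = 1.0) -> VelocitySequence:
    """Read a velocity sequence.

    Parameters
    ----------
    path : str or Path
        Directory of per-frame tables (+ ``meta.json``) or a single
        netCDF container.
    dialect : {"auto", "per-frame-table", "gridded-container"}
    scale : float
        Multiplier applied to coordinates and velocities at ingest (for
        pixel-unit exports); tables only.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "per-frame-table" if path.is_dir() else "gridded-container"
    if dialect == "gridded-container":
        if not path.exists():
            raise DataError(f"cannot read velocity container: {path} does not exist")
        ds = xr.open_dataset(path, engine="scipy")
        grid = _grid_from_xy(ds["x"].values, ds["y"].values)
        times = ds["time"].values.astype(float)
        frames = [
            VelocityFrame(
                grid,
                t,
                ds["u"].values[k],
                ds["v"].values[k],
                ds["valid"].values[k].astype(bool),
            )
            for k, t in enumerate(times)
        ]
        ds.close()
        return VelocitySequence(frames)
    if dialect != "per-frame-table":
        raise ConfigError(f"unknown dialect {dialect!r}")
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise DataError(f"cannot read velocity sequence: {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    files = sorted(path.glob("frame_*.csv"))
    times = meta["times"]
    if len(files) != len(times):
        raise DataError(f"{path}: meta lists {len(times)} frames, found {len(files)} tables")
    frames = [_frame_from_table(f, t, scale=scale) for f, t in zip(files, times)]
    return VelocitySequence(frames)


def write_velocity_sequence(seq: VelocitySequence, path, dialect: str = "per-frame-table") -> None:
    """Write a velocity sequence; the output re-reads bit-identically."""
    path = Path(path)
    if dialect == "gridded-container":
        grid = seq.grid
        ds = xr.Dataset(
            {
                "u": (("time", "y", "x"), np.stack([f.u for f in seq])),
                "v": (("time", "y", "x"), np.stack([f.v for f in seq])),
                "valid": (("time", "y", "x"), np.stack([f.valid for f in seq]).astype(np.int8)),
            },
            coords={"time": seq.times, "y": grid.y, "x": grid.x},
            attrs={"units": "m, s, m/s", "convention": "row=y, col=x"},
        )
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.to_netcdf(path, engine="scipy")
        return
    if dialect != "per-frame-table":
        raise ConfigError(f"unknown dialect {dialect!r}")
    path.mkdir(parents=True, exist_ok=True)
    grid = seq.grid if len(seq) else None
    for k, fr in enumerate(seq):
        X, Y = fr.grid.mesh()
        arr = np.column_stack(
            [X.ravel(), Y.ravel(), fr.u.ravel(), fr.v.ravel(), fr.valid.ravel().astype(float)]
        )
        np.savetxt(
            path / f"frame_{k:04d}.csv",
            arr,
            fmt=_FMT,
            delimiter=",",
            header="x,y,u,v,valid",
            comments="",
        )
    meta = {
        "n_frames": len(seq),
        "times": [float(f.t) for f in seq],
        "dt": None if np.isnan(seq.dt) else seq.dt,
        "units": "m, s, m/s",
    }
    if grid is not None:
        meta["grid"] = {"nx": grid.nx, "ny": grid.ny, "dx": grid.dx, "dy": grid.dy,
                        "origin": list(grid.origin)}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# masks


def _read_raster(p: Path) -> np.ndarray:
    if p.suffix.lower() in (".png", ".pgm", ".tif", ".tiff", ".bmp"):
        import imageio.v3 as iio

        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img[..., 0]
        # image row 0 is the top scanline; flip so row 0 is smallest y
        return np.flipud(img) != 0
    return np.loadtxt(p) != 0


def read_mask_sequence(paths: Sequence, grid: Grid2D) -> MaskSequence:
    """Read body masks (any nonzero pixel is body interior).

    ``paths`` may be a directory (all rasters inside, name-sorted) or an
    explicit list of files.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        d = Path(paths)
        paths = sorted(
            p for p in d.iterdir()
            if p.suffix.lower() in (".png", ".pgm", ".txt", ".csv", ".dat")
        )
    rasters = []
    for p in paths:
        m = _read_raster(Path(p))
        if m.shape != grid.shape:
            raise DataError(
                f"mask/grid shape mismatch: {Path(p).name} is {m.shape}, grid {grid.shape}"
            )
        rasters.append(m)
    return MaskSequence(grid, rasters)


def write_mask_sequence(masks: MaskSequence, path, fmt: str = "txt") -> list[Path]:
    """Write one raster per frame; ``fmt`` is ``"txt"`` (0/1 text) or ``"png"``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for k, m in enumerate(masks):
        if fmt == "png":
            import imageio.v3 as iio

            p = path / f"mask_{k:04d}.png"
            iio.imwrite(p, np.flipud(m.astype(np.uint8) * 255))
        else:
            p = path / f"mask_{k:04d}.txt"
            np.savetxt(p, m.astype(np.uint8), fmt="%d")
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# configuration

_CONFIG_KEYS = {
    "swim_axis_mode", "geometry_mode", "n_control_points", "surface_sample_offset",
    "min_valid_paths", "include_viscous", "edge_pressure", "dead_band",
    "rectify_lateral_power", "cycle_bounds", "rng_seed", "fixed_axis",
}


def read_config(path) -> tuple[AnalysisConfig, dict]:
    """Parse a TOML config file.

    Returns the :class:`AnalysisConfig` plus a dict of input paths / extra
    sections (``inputs``, ``synthetic`` ...) left for the pipeline.
    """
    import tomllib

    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except (OSError, tomllib.TOMLDecodeError) as e:
        raise ConfigError(f"cannot read config {path}: {e}") from e
    fluid = FluidProperties(**raw.get("fluid", {}))
    analysis = dict(raw.get("analysis", {}))
    unknown = set(analysis) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown analysis keys: {sorted(unknown)}")
    if "cycle_bounds" in analysis and analysis["cycle_bounds"] is not None:
        analysis["cycle_bounds"] = tuple(analysis["cycle_bounds"])
    if "fixed_axis" in analysis and analysis["fixed_axis"] is not None:
        analysis["fixed_axis"] = tuple(analysis["fixed_axis"])
    cfg = AnalysisConfig(fluid=fluid, **analysis)
    extra = {k: v for k, v in raw.items() if k not in ("fluid", "analysis")}
    return cfg, extra


# ---------------------------------------------------------------------------
# reports

_REQUIRED_REPORT_FIELDS = ("efficiency", "cycle_summary", "provenance")


def write_report(report: dict, path) -> None:
    """Write an analysis report: ``report.json`` plus per-frame CSV tables.

    ``report`` must carry ``efficiency``, ``cycle_summary`` and
    ``provenance``; an optional ``frames`` key (list of per-frame dicts)
    is written as ``frames.csv``.
    """
    missing = [k for k in _REQUIRED_REPORT_FIELDS if k not in report]
    if missing:
        raise DataError(f"report missing required fields: {missing}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = report.get("frames")
    head = {k: v for k, v in report.items() if k != "frames"}
    (path / "report.json").write_text(json.dumps(head, indent=1, sort_keys=True))
    if frames:
        pd.DataFrame(frames).to_csv(path / "frames.csv", index=False, float_format=_FMT)


def read_report(path) -> dict:
    path = Path(path)
    report = json.loads((path / "report.json").read_text())
    fcsv = path / "frames.csv"
    if fcsv.exists():
        report["frames"] = pd.read_csv(fcsv).to_dict(orient="records")
    return report
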