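"""Core gridded containers: measurement-plane geometry, velocity frames,
mask sequences, fluid properties and the analysis configuration.

Conventions
-----------
Node-centered regular lattice. ``x`` points rightward, ``y`` upward, and
arrays are indexed ``(row, col) = (y, x)``, shape ``(ny, nx)``. All
coordinates are in metres and velocities in metres per second; pixel-scale
conversion happens at ingest.

Validity is a collapsed boolean: ``False`` marks both body-interior nodes
and velocimetry dropouts — downstream stages only need "usable or not".
Non-finite velocity components force ``valid = False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "Grid2D",
    "FluidProperties",
    "VelocityFrame",
    "VelocitySequence",
    "MaskSequence",
    "AnalysisConfig",
]

#: uniform-dt tolerance for a velocity sequence, seconds
DT_TOL = 1e-9


@dataclass(frozen=True)
class Grid2D:
    """Regular node-centered 2-D lattice.

    Parameters
    ----------
    nx, ny : int
        Node counts along x and y; at least 3 each so second-order
        stencils exist.
    dx, dy : float
        Node spacing in metres (strictly positive).
    origin : tuple of float
        Physical coordinates of node ``(row=0, col=0)`` in metres.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ConfigError(f"grid needs nx,ny >= 3 (got {self.nx}x{self.ny})")
        if self.dx <= 0 or self.dy <= 0:
            raise ConfigError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.dy * np.arange(self.ny)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grid2D):
            return NotImplemented
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and np.isclose(self.dx, other.dx, rtol=1e-12)
            and np.isclose(self.dy, other.dy, rtol=1e-12)
            and np.allclose(self.origin, other.origin, rtol=1e-12, atol=1e-15)
        )

    def __hash__(self):
        return hash((self.nx, self.ny))


@dataclass(frozen=True)
class FluidProperties:
    """Density and dynamic viscosity of the working fluid.

    Defaults are fresh water at ~25 degC: rho = 998 kg/m^3,
    mu = 1.0e-3 Pa s.
    """

    rho: float = 998.0
    mu: float = 1.0e-3

    def __post_init__(self):
        if self.rho <= 0:
            raise ConfigError("density must be positive")
        if self.mu < 0:
            raise ConfigError("viscosity must be non-negative")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m^2/s."""
        return self.mu / self.rho


class VelocityFrame:
    """One gridded velocity snapshot.

    ``u``, ``v`` and ``valid`` all have shape ``(ny, nx)``. Nodes where
    either component is non-finite are forced invalid.
    """

    __slots__ = ("grid", "t", "u", "v", "valid")

    def __init__(self, grid: Grid2D, t: float, u, v, valid=None):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if u.shape != grid.shape or v.shape != grid.shape:
            raise DataError(
                f"velocity shape {u.shape}/{v.shape} does not match grid {grid.shape}"
            )
        if valid is None:
            valid = np.ones(grid.shape, dtype=bool)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != grid.shape:
                raise DataError("valid mask shape does not match grid")
        finite = np.isfinite(u) & np.isfinite(v)
        self.grid = grid
        self.t = float(t)
        self.u = u
        self.v = v
        self.valid = valid & finite

    def copy(self) -> "VelocityFrame":
        return VelocityFrame(self.grid, self.t, self.u.copy(), self.v.copy(), self.valid.copy())

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


class VelocitySequence:
    """Time-ordered velocity frames with uniform sampling interval.

    The inter-frame interval must be uniform to within 1e-9 s; pressure
    computation additionally requires at least three frames (checked where
    it is needed, not at construction, so short sequences can still be
    written to disk).
    """

    def __init__(self, frames: Sequence[VelocityFrame]):
        frames = sorted(frames, key=lambda f: f.t)
        self.frames = list(frames)
        if len(frames) >= 2:
            dts = np.diff([f.t for f in frames])
            if np.any(np.abs(dts - dts[0]) > DT_TOL):
                raise DataError("non-uniform sampling: frame interval varies by > 1e-9 s")
            self.dt = float(dts[0])
        else:
            self.dt = float("nan")
        grids = {f.grid for f in self.frames}
        if len(frames) and any(f.grid != self.frames[0].grid for f in self.frames):
            raise DataError("frames are not on a common grid")
        del grids

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> VelocityFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def grid(self) -> Grid2D:
        return self.frames[0].grid

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    def require_frames(self, n: int = 3) -> None:
        if len(self.frames) < n:
            raise DataError(f">={n} frames required (got {len(self.frames)})")


class MaskSequence:
    """Per-frame boolean body rasters (True = body interior) on one grid."""

    def __init__(self, grid: Grid2D, frames: Sequence[np.ndarray]):
        self.grid = grid
        self.frames = []
        for m in frames:
            m = np.asarray(m)
            if m.shape != grid.shape:
                raise DataError(
                    f"mask/grid shape mismatch: {m.shape} vs {grid.shape}"
                )
            self.frames.append(m.astype(bool))

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @classmethod
    def empty(cls, grid: Grid2D, n: int) -> "MaskSequence":
        return cls(grid, [np.zeros(grid.shape, dtype=bool) for _ in range(n)])


@dataclass
class AnalysisConfig:
    """Knobs for the full measurement-to-inference chain.

    Attributes
    ----------
    fluid : FluidProperties
    swim_axis_mode : {"auto", "fixed-vector"}
        How the swimming direction is obtained: least-squares fit of the
        centroid trajectory, or a user-supplied unit vector.
    fixed_axis : tuple or None
        The vector used when ``swim_axis_mode == "fixed-vector"``.
    geometry_mode : {"planar", "axisymmetric"}
        Per-unit-depth force integration (N/m) or surface-of-revolution
        integration of a meridional half-profile (N).
    n_control_points : int
        Contour control points (default 60, minimum 8).
    surface_sample_offset : float
        Outward pressure-sampling offset in grid cells (default 2; nodes
        hugging the mask inherit stencil damage).
    smooth_sigma : float
        Gaussian pre-smoothing of the velocity fields, in grid cells,
        applied before differentiation (default 0 = off). The median over
        rays absorbs impulsive outliers but not broadband measurement
        noise; 1-1.5 cells is the usual choice for noisy velocimetry.
    min_valid_paths : int
        Minimum surviving integration rays for a node's median pressure
        to count (1..8, default 3).
    include_viscous : bool
        Include mu*laplacian(u) in the momentum balance (default True).
    edge_pressure : {"integrated", "ambient"}
        Field-of-view edge treatment for the path integrator: edge values
        obtained by integrating the pressure gradient around the perimeter
        (mean anchored to ambient), or literal p = 0 at every edge node.
    dead_band : float
        |p| below which a surface element is classed neutral (Pa, default 0).
    cycle_bounds : tuple of float or None
        Optional (t0, t1) averaging window; should span whole cycles.
    rng_seed : int
        Seed for every stochastic element.
    """

    fluid: FluidProperties = field(default_factory=FluidProperties)
    swim_axis_mode: str = "auto"
    fixed_axis: tuple[float, float] | None = None
    geometry_mode: str = "planar"
    n_control_points: int = 60
    surface_sample_offset: float = 2.0
    min_valid_paths: int = 3
    include_viscous: bool = True
    smooth_sigma: float = 0.0
    edge_pressure: str = "integrated"
    dead_band: float = 0.0
    rectify_lateral_power: bool = False
    cycle_bounds: tuple[float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_control_points < 8:
            raise ConfigError("n_control_points must be >= 8")
        if not (1 <= self.min_valid_paths <= 8):
            raise ConfigError("min_valid_paths must be in 1..8")
        if self.swim_axis_mode not in ("auto", "fixed-vector"):
            raise ConfigError(f"unknown swim_axis_mode {self.swim_axis_mode!r}")
        if self.geometry_mode not in ("planar", "axisymmetric"):
            raise ConfigError(f"unknown geometry_mode {self.geometry_mode!r}")
        if self.edge_pressure not in ("integrated", "ambient"):
            raise ConfigError(f"unknown edge_pressure {self.edge_pressure!r}")
        if self.swim_axis_mode == "fixed-vector":
            if self.fixed_axis is None:
                raise ConfigError("fixed-vector mode needs fixed_axis")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)
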