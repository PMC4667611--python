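"""Analytic flows with known pressure, and synthetic swimmer datasets.

Three analytic cases validate the pressure stage quantitatively:

* ``taylor_green`` — the decaying Taylor–Green vortex lattice on
  [0, 2pi]^2: u = sin x cos y F(t), v = -cos x sin y F(t),
  F = exp(-2 nu t), p = (rho/4)(cos 2x + cos 2y) F^2.
* ``potential_cylinder`` — steady potential flow past a circular
  cylinder, surface pressure coefficient Cp = 1 - 4 sin^2(theta), with
  the cylinder interior masked. Being steady and irrotational it also
  exercises d'Alembert's paradox (zero net pressure force).
* ``lamb_oseen`` — a Gaussian-core vortex; the gauge pressure follows
  from the radial momentum balance dp/dr = rho u_theta^2 / r by
  quadrature with p(infinity) = 0. The core is a suction region: the
  pressure minimum sits at the center and is negative everywhere.

``synth_swimmer`` produces velocimetry + mask + ground-truth-contour
sequences for an undulating body carrying either a traveling wave of
lateral displacement (coordinated, control-like) or a standing wave
(uncoordinated, transect-like). The flow is kinematically prescribed,
not a Navier–Stokes solution: Gaussian-core vortex blobs are seeded at
the contour segment midpoints with circulation proportional to the local
ground-truth body-surface rotation (Gamma_i = Gamma0 * BSR_i * ds_i,
clipped at 3*Gamma0), so the near-body fluid rotation tracks the body
surface rotation exactly as the no-slip condition dictates. In traveling
mode the circulation pattern — and hence the suction cores it induces —
advances along the body at the wave phase speed; in standing mode it
pulses in place. The superposition of such blobs is exactly solenoidal
analytically, so the discrete divergence vanishes at truncation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from skimage.draw import polygon as _draw_polygon

from .errors import ConfigError, DataError
from .grids import Grid2D, MaskSequence, VelocityFrame, VelocitySequence
from .kinematics import BodyContour, resample_contour, surface_kinematics
from .pressure import PressureFrame

__all__ = [
    "AnalyticFlowCase",
    "SwimmerParams",
    "SyntheticSwimmerDataset",
    "taylor_green",
    "potential_cylinder",
    "lamb_oseen",
    "synth_swimmer",
    "add_measurement_noise",
    "taylor_green_grid",
]


@dataclass
class AnalyticFlowCase:
    """A velocity sequence bundled with its exact gauge pressure."""

    name: str
    velocity: VelocitySequence
    pressure_truth: list[PressureFrame]
    mask: MaskSequence | None = None


def taylor_green_grid(n: int) -> Grid2D:
    """An n x n grid spanning [0, 2pi]^2 (node-centered, inclusive ends)."""
    h = 2 * np.pi / (n - 1)
    return Grid2D(nx=n, ny=n, dx=h, dy=h, origin=(0.0, 0.0))


def taylor_green(
    grid: Grid2D, rho: float = 1000.0, nu: float = 1e-6, times: Sequence[float] = (0.0,)
) -> AnalyticFlowCase:
    """Decaying Taylor–Green vortex lattice on [0, 2pi]^2."""
    x_end = grid.origin[0] + (grid.nx - 1) * grid.dx
    y_end = grid.origin[1] + (grid.ny - 1) * grid.dy
    if (
        abs(grid.origin[0]) > 1e-9
        or abs(grid.origin[1]) > 1e-9
        or abs(x_end - 2 * np.pi) > 1e-6
        or abs(y_end - 2 * np.pi) > 1e-6
    ):
        raise DataError("domain mismatch: Taylor–Green needs a grid spanning [0, 2pi]^2")
    X, Y = grid.mesh()
    frames, truths = [], []
    for t in times:
        F = np.exp(-2.0 * nu * t)
        u = np.sin(X) * np.cos(Y) * F
        v = -np.cos(X) * np.sin(Y) * F
        p = 0.25 * rho * (np.cos(2 * X) + np.cos(2 * Y)) * F**2
        frames.append(VelocityFrame(grid, t, u, v))
        truths.append(
            PressureFrame(grid, t, p, np.ones(grid.shape, bool),
                          np.full(grid.shape, 8, np.int16))
        )
    return AnalyticFlowCase("taylor_green", VelocitySequence(frames), truths)


def potential_cylinder(
    grid: Grid2D,
    U_inf: float,
    R: float,
    rho: float = 1000.0,
    center: tuple[float, float] | None = None,
    n_frames: int = 3,
    dt: float = 0.01,
) -> AnalyticFlowCase:
    """Steady potential flow (+x) past a circular cylinder of radius R.

    Returns >= 3 identical frames so the temporal term is exactly zero.
    The cylinder interior is masked and the velocity there is NaN.
    """
    if R < 5 * grid.dx:
        raise ConfigError("cylinder radius must be at least 5 grid cells")
    if center is None:
        center = (
            grid.origin[0] + 0.5 * (grid.nx - 1) * grid.dx,
            grid.origin[1] + 0.5 * (grid.ny - 1) * grid.dy,
        )
    x_end = grid.origin[0] + (grid.nx - 1) * grid.dx
    y_end = grid.origin[1] + (grid.ny - 1) * grid.dy
    clearance = 2 * max(grid.dx, grid.dy)
    if (
        center[0] - R < grid.origin[0] + clearance
        or center[0] + R > x_end - clearance
        or center[1] - R < grid.origin[1] + clearance
        or center[1] + R > y_end - clearance
    ):
        raise ConfigError("insufficient clearance: cylinder touches the boundary")
    X, Y = grid.mesh()
    xr = X - center[0]
    yr = Y - center[1]
    r2 = xr**2 + yr**2
    r2 = np.where(r2 == 0, np.nan, r2)
    u = U_inf * (1.0 + R**2 * (yr**2 - xr**2) / r2**2)
    v = U_inf * (-2.0 * R**2 * xr * yr / r2**2)
    inside = r2 < R**2
    u = np.where(inside, np.nan, u)
    v = np.where(inside, np.nan, v)
    p = 0.5 * rho * (U_inf**2 - (u**2 + v**2))
    mask = MaskSequence(grid, [inside] * n_frames)
    frames = [VelocityFrame(grid, k * dt, u, v, ~inside) for k in range(n_frames)]
    truths = [
        PressureFrame(grid, k * dt, p, ~inside, np.full(grid.shape, 8, np.int16))
        for k in range(n_frames)
    ]
    return AnalyticFlowCase("potential_cylinder", VelocitySequence(frames), truths, mask)


def lamb_oseen_pressure_profile(
    Gamma: float, r_c: float, rho: float, r: np.ndarray
) -> np.ndarray:
    """Gauge pressure p(r) of a Gaussian-core vortex by radial quadrature
    of dp/dr = rho u_theta^2 / r, anchored with the analytic far-field
    tail p(r) -> -rho Gamma^2 / (8 pi^2 r^2)."""
    if Gamma == 0:
        return np.zeros_like(r)
    r_max = max(float(np.max(r)) * 1.5, 10 * r_c)
    rt = np.linspace(0.0, r_max, 6000)
    with np.errstate(divide="ignore", invalid="ignore"):
        utheta = Gamma / (2 * np.pi * rt) * (1.0 - np.exp(-(rt**2) / r_c**2))
        integrand = rho * utheta**2 / rt
    integrand[0] = 0.0  # u_theta ~ r near the axis, integrand -> 0
    I = cumulative_trapezoid(integrand, rt, initial=0.0)
    p_tail = -rho * Gamma**2 / (8 * np.pi**2 * r_max**2)
    p_table = p_tail - (I[-1] - I)
    return np.interp(r, rt, p_table)


def lamb_oseen(
    grid: Grid2D,
    Gamma: float,
    r_c: float,
    center: tuple[float, float] | None = None,
    rho: float = 1000.0,
    nu: float = 0.0,
    times: Sequence[float] = (0.0,),
) -> AnalyticFlowCase:
    """Gaussian-core (Lamb–Oseen) vortex; viscous spreading when nu > 0.

    Gamma = 0 returns a quiescent case with zero gauge pressure.
    """
    if r_c <= 0:
        raise ConfigError("core radius must be positive")
    if center is None:
        center = (
            grid.origin[0] + 0.5 * (grid.nx - 1) * grid.dx,
            grid.origin[1] + 0.5 * (grid.ny - 1) * grid.dy,
        )
    x_end = grid.origin[0] + (grid.nx - 1) * grid.dx
    y_end = grid.origin[1] + (grid.ny - 1) * grid.dy
    if (
        center[0] - 2 * r_c < grid.origin[0]
        or center[0] + 2 * r_c > x_end
        or center[1] - 2 * r_c < grid.origin[1]
        or center[1] + 2 * r_c > y_end
    ):
        raise ConfigError("insufficient clearance: vortex core not fully interior")
    X, Y = grid.mesh()
    xr = X - center[0]
    yr = Y - center[1]
    r = np.hypot(xr, yr)
    frames, truths = [], []
    for t in times:
        rc_t = np.sqrt(r_c**2 + 4 * nu * t)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = Gamma / (2 * np.pi * r**2) * (1.0 - np.exp(-(r**2) / rc_t**2))
        f = np.where(r > 0, f, 0.0)
        u = -f * yr
        v = f * xr
        p = lamb_oseen_pressure_profile(Gamma, rc_t, rho, r)
        frames.append(VelocityFrame(grid, t, u, v))
        truths.append(
            PressureFrame(grid, t, p, np.ones(grid.shape, bool),
                          np.full(grid.shape, 8, np.int16))
        )
    return AnalyticFlowCase("lamb_oseen", VelocitySequence(frames), truths)


# ---------------------------------------------------------------------------
# synthetic swimmer


def _default_half_width(L: float, w0: float) -> Callable[[np.ndarray], np.ndarray]:
    def w(xi):
        s = 2.0 * np.asarray(xi) / L - 1.0
        return w0 * np.sqrt(np.clip(1.0 - s**2, 0.0, None))

    return w


@dataclass
class SwimmerParams:
    """Kinematic parameters of the synthetic swimmer.

    Defaults mimic a 12 cm larval-lamprey-scale animal: body length
    L = 0.12 m, one body wavelength, period 0.4 s, tail-biased amplitude
    envelope A(xi) = a0 + a1 xi + a2 xi^2 reaching ~8% L at the tail,
    and a swimming speed of 2 body lengths per second in traveling mode
    versus 1.2 in standing mode (prescribed, not emergent).
    ``xi`` is the body coordinate from the nose, metres.
    """

    L: float = 0.12
    lam: float = 0.12
    T_p: float = 0.4
    a0: float = 0.002
    a1: float = 0.0
    a2: float = 0.556
    w0: float = 0.006
    wave_mode: str = "traveling"
    Gamma0: float = 0.35
    r_c: float = 0.008
    blob_offset: float = 1.0  # core radii outward along the surface normal
    n_frames: int = 22
    seed: int = 0
    swim_speed: float | None = None  # m/s; None -> mode default
    n_outline: int = 200

    def __post_init__(self):
        if min(self.L, self.lam, self.T_p, self.r_c) <= 0:
            raise ConfigError("L, lambda, T_p, r_c must be positive")
        if self.wave_mode not in ("traveling", "standing"):
            raise ConfigError(f"unknown wave_mode {self.wave_mode!r}")

    @property
    def U(self) -> float:
        if self.swim_speed is not None:
            return self.swim_speed
        return (2.0 if self.wave_mode == "traveling" else 1.2) * self.L

    def amplitude(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        return self.a0 + self.a1 * xi + self.a2 * xi**2

    def midline_y(self, xi, t: float) -> np.ndarray:
        """Lateral midline displacement in the body frame."""
        xi = np.asarray(xi, dtype=float)
        if self.wave_mode == "traveling":
            return self.amplitude(xi) * np.sin(2 * np.pi * (xi / self.lam - t / self.T_p))
        return (
            self.amplitude(xi)
            * np.sin(2 * np.pi * xi / self.lam)
            * np.cos(2 * np.pi * t / self.T_p)
        )

    def half_width(self, xi) -> np.ndarray:
        return _default_half_width(self.L, self.w0)(xi)


@dataclass
class SyntheticSwimmerDataset:
    velocity: VelocitySequence
    masks: MaskSequence
    contours: list[BodyContour]  # ground truth, n_control points each
    params: SwimmerParams


def _outline(params: SwimmerParams, t: float, x_nose: float) -> np.ndarray:
    """Closed counterclockwise outline polygon at time t (lab frame).

    The swimmer translates toward -x at speed U; the body coordinate xi
    runs noseward-to-tailward in +x.
    """
    xi = np.linspace(0.0, params.L, params.n_outline)
    y = params.midline_y(xi, t)
    dydxi = np.gradient(y, xi)
    norm = np.hypot(1.0, dydxi)
    w = params.half_width(xi)
    xm = x_nose + xi
    # midline normal (-y', 1)/|.|; offset by +/- w along it
    upper = np.column_stack([xm - w * (dydxi / norm), y + w * (1.0 / norm)])
    lower = np.column_stack([xm + w * (dydxi / norm), y - w * (1.0 / norm)])
    # CCW: nose -> lower side (xi increasing) -> tail -> upper side back
    poly = np.vstack([lower, upper[::-1]])
    # drop consecutive duplicates (w=0 at both ends)
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-12
    poly = poly[keep]
    x, yv = poly[:, 0], poly[:, 1]
    if 0.5 * np.sum(x * np.roll(yv, -1) - np.roll(x, -1) * yv) < 0:
        poly = poly[::-1]
    return poly


def _rasterize(poly: np.ndarray, grid: Grid2D) -> np.ndarray:
    cols = (poly[:, 0] - grid.origin[0]) / grid.dx
    rows = (poly[:, 1] - grid.origin[1]) / grid.dy
    rr, cc = _draw_polygon(rows, cols, shape=grid.shape)
    m = np.zeros(grid.shape, dtype=bool)
    m[rr, cc] = True
    return m


def _truth_contour(params: SwimmerParams, t: float, n: int) -> BodyContour:
    x_nose = -params.U * t
    c = resample_contour(_outline(params, t, x_nose), n=n, s_hat=(-1.0, 0.0), t=t)
    return c


def _blob_velocity(
    X: np.ndarray, Y: np.ndarray, centers: np.ndarray, gammas: np.ndarray, r_c: float
) -> tuple[np.ndarray, np.ndarray]:
    u = np.zeros_like(X)
    v = np.zeros_like(Y)
    for (cx, cy), gam in zip(centers, gammas):
        if gam == 0:
            continue
        xr = X - cx
        yr = Y - cy
        r2 = xr**2 + yr**2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = gam / (2 * np.pi * r2) * (1.0 - np.exp(-r2 / r_c**2))
        f = np.where(r2 > 0, f, 0.0)
        u -= f * yr
        v += f * xr
    return u, v


def swimmer_grid(params: SwimmerParams, dt: float, dx: float = 0.0015) -> Grid2D:
    """A grid sized to the swimmer's full trajectory plus clearance."""
    travel = params.U * params.n_frames * dt
    margin = 5 * params.w0
    x_lo = -travel - margin
    x_hi = params.L + margin
    y_half = float(params.amplitude(params.L)) + params.w0 + margin
    nx = int(np.ceil((x_hi - x_lo) / dx)) + 1
    ny = int(np.ceil(2 * y_half / dx)) + 1
    return Grid2D(nx=nx, ny=ny, dx=dx, dy=dx, origin=(x_lo, -y_half))


def synth_swimmer(
    params: SwimmerParams,
    grid: Grid2D,
    dt: float,
    n_control: int = 60,
) -> SyntheticSwimmerDataset:
    """Generate a velocimetry + mask + ground-truth-contour sequence.

    At each frame the body outline and its masks are built analytically;
    vortex blobs sit at the 60-point contour segment midpoints with
    circulation Gamma0 * BSR * ds (sign following the rotation sense,
    clipped at 3*Gamma0), where the ground-truth BSR comes from contours
    evaluated a small time step apart. Nodes inside the body are invalid.
    """
    x_end = grid.origin[0] + (grid.nx - 1) * grid.dx
    y_end = grid.origin[1] + (grid.ny - 1) * grid.dy
    width = 2 * params.w0
    times = np.arange(params.n_frames) * dt
    # clearance check over the whole trajectory
    for t in (times[0], times[-1]):
        poly = _outline(params, t, -params.U * t)
        if (
            poly[:, 0].min() < grid.origin[0] + 2 * width
            or poly[:, 0].max() > x_end - 2 * width
            or poly[:, 1].min() < grid.origin[1] + 2 * width
            or poly[:, 1].max() > y_end - 2 * width
        ):
            raise ConfigError("body leaves domain (amplitude or travel exceeds clearance)")

    X, Y = grid.mesh()
    delta = params.T_p / 1000.0
    frames, masks, contours = [], [], []
    for t in times:
        c = _truth_contour(params, t, n_control)
        c_prev = _truth_contour(params, t - delta, n_control)
        c_next = _truth_contour(params, t + delta, n_control)
        kin = surface_kinematics(c_prev, c, c_next, dt=delta)
        gam = params.Gamma0 * kin.bsr * c.seg_lengths
        gam = np.clip(gam, -3 * params.Gamma0, 3 * params.Gamma0)
        mids = 0.5 * (c.points + np.roll(c.points, -1, axis=0))
        nmid = 0.5 * (c.normals + np.roll(c.normals, -1, axis=0))
        nmid /= np.linalg.norm(nmid, axis=1, keepdims=True)
        # cores sit in the fluid, one core radius off the surface
        mids = mids + params.blob_offset * params.r_c * nmid
        u, v = _blob_velocity(X, Y, mids, gam, params.r_c)
        mask = _rasterize(_outline(params, t, -params.U * t), grid)
        u = np.where(mask, np.nan, u)
        v = np.where(mask, np.nan, v)
        frames.append(VelocityFrame(grid, float(t), u, v, ~mask))
        masks.append(mask)
        contours.append(c)
    return SyntheticSwimmerDataset(
        velocity=VelocitySequence(frames),
        masks=MaskSequence(grid, masks),
        contours=contours,
        params=params,
    )


def add_measurement_noise(
    seq: VelocitySequence, sigma: float, seed: int = 0
) -> VelocitySequence:
    """Add i.i.d. zero-mean Gaussian noise (std ``sigma`` m/s) to both
    velocity components at valid nodes; reproducible under a fixed seed."""
    if sigma < 0:
        raise ConfigError("noise sigma must be non-negative")
    if sigma == 0:
        return VelocitySequence([f.copy() for f in seq])
    rng = np.random.default_rng(seed)
    frames = []
    for f in seq:
        u = f.u.copy()
        v = f.v.copy()
        u[f.valid] += rng.normal(0.0, sigma, size=int(f.valid.sum()))
        v[f.valid] += rng.normal(0.0, sigma, size=int(f.valid.sum()))
        frames.append(VelocityFrame(f.grid, f.t, u, v, f.valid.copy()))
    return VelocitySequence(frames)
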