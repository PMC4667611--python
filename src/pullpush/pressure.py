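"""Gauge pressure fields from velocity sequences.

The momentum balance of an incompressible planar flow gives the pressure
gradient at every node,

    grad p = -rho * (du/dt + (u . grad) u) + mu * laplacian(u),

with the material acceleration from three consecutive frames (central in
time) and second-order central differences in space. The gradient is then
integrated along eight straight rays (E, NE, N, NW, W, SW, S, SE, along
grid lines and diagonals) from each node to the edge of the field of
view, accumulating -int(grad p . dl) by the trapezoidal rule from the
edge inward, and the node's pressure is the median of the surviving ray
results. The median makes the estimate robust: a large error on a single
ray leaves the output untouched as long as most rays agree.

Rays that cross a masked or otherwise invalid node are discarded; nodes
with fewer than ``min_valid_paths`` surviving rays are marked invalid and
filled by nearest-valid interpolation, flagged in
``PressureFrame.interpolated``.

Field-of-view edge values anchor the rays. By default they are obtained
by integrating the computed pressure gradient around the perimeter
(closure error distributed linearly, mean anchored at ambient 0), which
keeps the method exact for fields whose boundary pressure is not
constant; ``edge_pressure="ambient"`` instead imposes a literal p = 0 at
every edge node, appropriate when the edges are genuinely far-field.

``poisson_pressure_oracle`` is an independent route to the same field —
a direct sparse solve of div(grad p) — used for validation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .errors import DataError, NumericalError
from .grids import AnalysisConfig, FluidProperties, Grid2D, MaskSequence, VelocityFrame, VelocitySequence

__all__ = [
    "MaterialAcceleration",
    "PressureGradientField",
    "PressureFrame",
    "material_acceleration",
    "pressure_gradient",
    "eight_path_pressures",
    "integrate_pressure",
    "poisson_pressure_oracle",
    "pressure_sequence",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: ray directions (di, dj): E, W, N, S, NE, SE, NW, SW
_DIRS = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, 1), (1, -1), (-1, -1))


@dataclass
class MaterialAcceleration:
    grid: Grid2D
    t: float
    ax: np.ndarray
    ay: np.ndarray
    valid: np.ndarray


@dataclass
class PressureGradientField:
    grid: Grid2D
    t: float
    gx: np.ndarray
    gy: np.ndarray
    valid: np.ndarray


@dataclass
class PressureFrame:
    """Gauge pressure (Pa, 0 = ambient) with per-node bookkeeping.

    ``valid`` is False inside the body mask and wherever fewer than the
    required number of rays survived; those nodes carry nearest-valid
    fill values and are flagged in ``interpolated``.
    """

    grid: Grid2D
    t: float
    p: np.ndarray
    valid: np.ndarray
    n_paths_used: np.ndarray
    interpolated: np.ndarray | None = None


# ---------------------------------------------------------------------------


def material_acceleration(
    prev: VelocityFrame, curr: VelocityFrame, nxt: VelocityFrame, dt: float | None = None
) -> MaterialAcceleration:
    """Du/Dt at the middle frame: central time difference plus the
    convective term from central spatial differences on ``curr``."""
    g = curr.grid
    if prev.grid != g or nxt.grid != g:
        raise DataError("frames are not on a common grid")
    if dt is None:
        dt = (nxt.t - prev.t) / 2.0
    if dt <= 0:
        raise DataError("dt must be positive")
    dudt = (nxt.u - prev.u) / (2 * dt)
    dvdt = (nxt.v - prev.v) / (2 * dt)
    dudy, dudx = np.gradient(curr.u, g.dy, g.dx, edge_order=2)
    dvdy, dvdx = np.gradient(curr.v, g.dy, g.dx, edge_order=2)
    ax = dudt + curr.u * dudx + curr.v * dudy
    ay = dvdt + curr.u * dvdx + curr.v * dvdy
    valid = prev.valid & curr.valid & nxt.valid
    valid = ndimage.binary_erosion(valid, structure=_CROSS, border_value=1)
    valid &= np.isfinite(ax) & np.isfinite(ay)
    return MaterialAcceleration(grid=g, t=curr.t, ax=ax, ay=ay, valid=valid)


def _laplacian(f: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """5-point Laplacian; edge rows/cols replicate the adjacent interior
    value (the viscous term is a small correction there)."""
    lap = np.empty_like(f)
    lap[1:-1, 1:-1] = (f[1:-1, 2:] - 2 * f[1:-1, 1:-1] + f[1:-1, :-2]) / dx**2 + (
        f[2:, 1:-1] - 2 * f[1:-1, 1:-1] + f[:-2, 1:-1]
    ) / dy**2
    lap[0, 1:-1] = lap[1, 1:-1]
    lap[-1, 1:-1] = lap[-2, 1:-1]
    lap[:, 0] = lap[:, 1]
    lap[:, -1] = lap[:, -2]
    return lap


def pressure_gradient(
    accel: MaterialAcceleration,
    curr: VelocityFrame,
    fluid: FluidProperties,
    include_viscous: bool = True,
) -> PressureGradientField:
    """grad p = -rho Du/Dt + mu laplacian(u)."""
    g = accel.grid
    gx = -fluid.rho * accel.ax
    gy = -fluid.rho * accel.ay
    if include_viscous and fluid.mu > 0:
        gx = gx + fluid.mu * _laplacian(curr.u, g.dx, g.dy)
        gy = gy + fluid.mu * _laplacian(curr.v, g.dx, g.dy)
    valid = accel.valid & np.isfinite(gx) & np.isfinite(gy)
    return PressureGradientField(grid=g, t=accel.t, gx=gx, gy=gy, valid=valid)


# ---------------------------------------------------------------------------
# path integration


def _edge_pressures(
    gx: np.ndarray, gy: np.ndarray, valid: np.ndarray, grid: Grid2D, mode: str
) -> np.ndarray:
    """Pressure at the field-of-view edge nodes (NaN elsewhere/invalid)."""
    ny, nx = valid.shape
    edge = np.full((ny, nx), np.nan)
    ring_ij = (
        [(0, j) for j in range(nx)]
        + [(i, nx - 1) for i in range(1, ny)]
        + [(ny - 1, j) for j in range(nx - 2, -1, -1)]
        + [(i, 0) for i in range(ny - 2, 0, -1)]
    )
    ii = np.array([ij[0] for ij in ring_ij])
    jj = np.array([ij[1] for ij in ring_ij])
    ring_ok = valid[ii, jj] & np.isfinite(gx[ii, jj]) & np.isfinite(gy[ii, jj])
    if mode == "integrated" and ring_ok.all():
        x = grid.origin[0] + jj * grid.dx
        y = grid.origin[1] + ii * grid.dy
        gxs, gys = gx[ii, jj], gy[ii, jj]
        # segments k -> k+1 plus the closure segment back to the start
        dx_seg = np.diff(np.append(x, x[0]))
        dy_seg = np.diff(np.append(y, y[0]))
        gxm = 0.5 * (gxs + np.roll(gxs, -1))
        gym = 0.5 * (gys + np.roll(gys, -1))
        dp = gxm * dx_seg + gym * dy_seg
        p = np.concatenate([[0.0], np.cumsum(dp[:-1])])
        closure = float(dp.sum())  # should vanish for a true gradient
        arclen = np.concatenate([[0.0], np.cumsum(np.hypot(dx_seg, dy_seg)[:-1])])
        total = arclen[-1] + np.hypot(dx_seg[-1], dy_seg[-1])
        p = p - closure * arclen / total
        p = p - p.mean()  # ambient on average
        edge[ii, jj] = p
    else:
        edge[ii[ring_ok], jj[ring_ok]] = 0.0
    return edge


def eight_path_pressures(
    grad: PressureGradientField, edge_p: np.ndarray
) -> np.ndarray:
    """The eight per-ray pressure estimates, shape ``(8, ny, nx)``.

    Entry ``k`` integrates along ray direction ``k`` from the node to the
    field-of-view edge; NaN marks rays blocked by invalid nodes.
    """
    g = grad.grid
    dx, dy = g.dx, g.dy
    ny, nx = grad.valid.shape
    gxv = np.where(grad.valid, grad.gx, np.nan)
    gyv = np.where(grad.valid, grad.gy, np.nan)
    out = np.empty((8, ny, nx))
    for k, (di, dj) in enumerate(_DIRS):
        p = np.full((ny, nx), np.nan)
        if dj != 0:
            js = range(nx - 1, -1, -1) if dj == 1 else range(nx)
            for j in js:
                jn = j + dj
                if jn < 0 or jn >= nx:
                    p[:, j] = edge_p[:, j]
                    continue
                if di == 0:
                    inc = 0.5 * (gxv[:, j] + gxv[:, jn]) * (dj * dx)
                    p[:, j] = p[:, jn] - inc
                elif di == 1:
                    inc = 0.5 * (
                        (gxv[:-1, j] + gxv[1:, jn]) * (dj * dx)
                        + (gyv[:-1, j] + gyv[1:, jn]) * dy
                    )
                    p[:-1, j] = p[1:, jn] - inc
                    p[-1, j] = edge_p[-1, j]
                else:
                    inc = 0.5 * (
                        (gxv[1:, j] + gxv[:-1, jn]) * (dj * dx)
                        + (gyv[1:, j] + gyv[:-1, jn]) * (-dy)
                    )
                    p[1:, j] = p[:-1, jn] - inc
                    p[0, j] = edge_p[0, j]
        else:
            irange = range(ny - 1, -1, -1) if di == 1 else range(ny)
            for i in irange:
                inr = i + di
                if inr < 0 or inr >= ny:
                    p[i, :] = edge_p[i, :]
                    continue
                inc = 0.5 * (gyv[i, :] + gyv[inr, :]) * (di * dy)
                p[i, :] = p[inr, :] - inc
        out[k] = p
    return out


def integrate_pressure(
    grad: PressureGradientField,
    mask: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> PressureFrame:
    """Median-of-eight-path pressure integration.

    ``mask`` (True = body interior) forces nodes invalid in addition to
    the gradient field's own validity. Returns a :class:`PressureFrame`
    whose invalid nodes are filled by nearest-valid interpolation and
    flagged.
    """
    config = config or AnalysisConfig()
    valid = grad.valid.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != valid.shape:
            raise DataError("mask/grid shape mismatch")
        valid &= ~mask
    if not valid.any():
        raise NumericalError("no computable nodes: all-invalid field")
    g2 = PressureGradientField(grad.grid, grad.t, grad.gx, grad.gy, valid)
    edge_p = _edge_pressures(grad.gx, grad.gy, valid, grad.grid, config.edge_pressure)
    stack = eight_path_pressures(g2, edge_p)
    n_paths = np.isfinite(stack).sum(axis=0).astype(np.int16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        p_med = np.nanmedian(stack, axis=0)
    ok = valid & (n_paths >= config.min_valid_paths) & np.isfinite(p_med)
    if not ok.any():
        raise NumericalError("no computable nodes: every node lost too many rays")
    # nearest-valid fill for shadowed / low-path nodes
    _, (fi, fj) = ndimage.distance_transform_edt(
        ~ok, sampling=(grad.grid.dy, grad.grid.dx), return_indices=True
    )
    p_fill = p_med[fi, fj]
    interpolated = ~ok
    return PressureFrame(
        grid=grad.grid,
        t=grad.t,
        p=p_fill,
        valid=ok,
        n_paths_used=np.where(valid, n_paths, 0),
        interpolated=interpolated,
    )


# ---------------------------------------------------------------------------
# Poisson oracle (validation only)


def poisson_pressure_oracle(
    grad: PressureGradientField,
    mask: np.ndarray | None = None,
    bc: str = "dirichlet",
) -> PressureFrame:
    """Independent pressure route: solve div(grad p) = div g.

    Finite-volume discretisation on the valid nodes. ``bc="dirichlet"``
    pins p = 0 on the field-of-view edge nodes (compact-support fields);
    ``bc="neumann"`` uses gradient-flux conditions on every boundary
    (fields with non-trivial edge pressure), pins one node and removes
    the mean afterwards. Internal mask boundaries always get the Neumann
    treatment (faces dropped consistently from both sides).
    """
    g = grad.grid
    valid = grad.valid.copy()
    if mask is not None:
        valid &= ~np.asarray(mask, dtype=bool)
    ny, nx = valid.shape
    ids = -np.ones((ny, nx), dtype=int)
    ids[valid] = np.arange(valid.sum())
    n = int(valid.sum())
    if n == 0:
        raise NumericalError("no computable nodes: all-invalid field")
    gx = np.where(valid, grad.gx, np.nan)
    gy = np.where(valid, grad.gy, np.nan)

    on_edge = np.zeros((ny, nx), dtype=bool)
    on_edge[0, :] = on_edge[-1, :] = True
    on_edge[:, 0] = on_edge[:, -1] = True

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    dirichlet = valid & on_edge if bc == "dirichlet" else np.zeros_like(valid)
    if bc == "dirichlet" and not dirichlet.any():
        raise NumericalError("ill-posed: no Dirichlet nodes on the domain edge")

    ii, jj = np.nonzero(valid & ~dirichlet)
    for di, dj, h, gcomp in ((0, 1, g.dx, gx), (0, -1, g.dx, gx), (1, 0, g.dy, gy), (-1, 0, g.dy, gy)):
        ni, nj = ii + di, jj + dj
        inside = (ni >= 0) & (ni < ny) & (nj >= 0) & (nj < nx)
        nb_valid = np.zeros(len(ii), dtype=bool)
        nb_valid[inside] = valid[ni[inside], nj[inside]]
        a = ids[ii[nb_valid], jj[nb_valid]]
        b = ids[ni[nb_valid], nj[nb_valid]]
        rows.extend(a.tolist())
        cols.extend(b.tolist())
        vals.extend((np.full(len(a), 1.0 / h**2)).tolist())
        np.add.at(diag, a, -1.0 / h**2)
        sgn = float(di + dj)
        face_g = 0.5 * (gcomp[ii[nb_valid], jj[nb_valid]] + gcomp[ni[nb_valid], nj[nb_valid]])
        np.add.at(rhs, a, sgn * face_g / h)
        # invalid/out-of-domain faces: Neumann flux from g cancels on both sides

    all_ids = np.arange(n)
    rows.extend(all_ids.tolist())
    cols.extend(all_ids.tolist())
    vals.extend(diag.tolist())

    if bc == "dirichlet":
        d_ids = ids[dirichlet]
        rows.extend(d_ids.tolist())
        cols.extend(d_ids.tolist())
        vals.extend([1.0] * len(d_ids))
    else:
        pin = 0
        # overwrite the pinned node's row with identity
        rows_a = np.array(rows)
        keep = rows_a != pin
        rows = rows_a[keep].tolist()
        cols = np.array(cols)[keep].tolist()
        vals = np.array(vals)[keep].tolist()
        rows.append(pin)
        cols.append(pin)
        vals.append(1.0)
        rhs[pin] = 0.0

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        sol = spsolve(A, rhs)
    except Exception as e:  # pragma: no cover
        raise NumericalError(f"ill-posed pressure system: {e}") from e
    if not np.all(np.isfinite(sol)):
        raise NumericalError("ill-posed pressure system: singular solve")
    if bc != "dirichlet":
        sol = sol - sol.mean()
    p = np.full((ny, nx), np.nan)
    p[valid] = sol
    return PressureFrame(
        grid=g, t=grad.t, p=p, valid=valid,
        n_paths_used=np.where(valid, 8, 0).astype(np.int16),
        interpolated=np.zeros_like(valid),
    )


# ---------------------------------------------------------------------------


def smooth_velocity(seq: VelocitySequence, sigma_cells: float) -> VelocitySequence:
    """Mask-aware Gaussian smoothing of the velocity components.

    Uses normalised convolution so invalid (masked/dropout) nodes
    neither contribute nor bleed values into their neighbourhood; the
    validity pattern itself is unchanged.
    """
    if sigma_cells <= 0:
        return seq
    frames = []
    for f in seq:
        w = f.valid.astype(float)
        wn = ndimage.gaussian_filter(w, sigma_cells, mode="nearest")
        with np.errstate(invalid="ignore"):
            u = ndimage.gaussian_filter(np.where(f.valid, f.u, 0.0), sigma_cells, mode="nearest") / wn
            v = ndimage.gaussian_filter(np.where(f.valid, f.v, 0.0), sigma_cells, mode="nearest") / wn
        u = np.where(f.valid, u, np.nan)
        v = np.where(f.valid, v, np.nan)
        frames.append(VelocityFrame(f.grid, f.t, u, v, f.valid.copy()))
    return VelocitySequence(frames)


def pressure_sequence(
    seq: VelocitySequence,
    masks: MaskSequence | None,
    fluid: FluidProperties,
    config: AnalysisConfig | None = None,
) -> list[PressureFrame]:
    """One pressure frame per interior velocity frame (the first and last
    frame lack a centered time stencil and are not emitted)."""
    config = config or AnalysisConfig()
    seq.require_frames(3)
    if masks is not None and len(masks) != len(seq):
        raise DataError("mask sequence length does not match velocity sequence")
    if config.smooth_sigma > 0:
        seq = smooth_velocity(seq, config.smooth_sigma)
    out = []
    for k in range(1, len(seq) - 1):
        accel = material_acceleration(seq[k - 1], seq[k], seq[k + 1], seq.dt)
        grad = pressure_gradient(accel, seq[k], fluid, config.include_viscous)
        mask = masks[k] if masks is not None else None
        out.append(integrate_pressure(grad, mask=mask, config=config))
    return out
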