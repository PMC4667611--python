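"""Body-surface kinematics from mask sequences and velocity fields.

The body outline is traced from the binary mask at sub-cell resolution,
resampled to a fixed number of equally spaced control points (60 by
default), and differentiated in time to obtain the surface velocity
``u_body`` and the body surface rotation BSR — the angular velocity, in
the lab frame, of each line segment connecting adjacent control points.
The body surface vorticity BSV is the fluid vorticity at the valid grid
node nearest each control point. Under the no-slip condition the fluid
immediately adjacent to the surface rotates with the surface, so BSV and
BSR should agree in sign and, after per-frame normalisation, in pattern;
that correspondence is what the traveling-wave swimmer exploits.

Index correspondence across frames is by arc-length position from an
anterior anchor (the most-anterior point along the swimming direction,
or max-x before the swimming direction is known), not by feature
tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DataError, NumericalError
from .grids import Grid2D, VelocityFrame

__all__ = [
    "BodyContour",
    "ContourKinematics",
    "SwimFrame",
    "VorticityFrame",
    "extract_contour",
    "resample_contour",
    "surface_kinematics",
    "vorticity_field",
    "body_surface_vorticity",
    "swim_frame",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BodyContour:
    """Closed body outline as ``n`` ordered control points (counter-
    clockwise, anterior first), with outward unit normals and segment
    lengths ``ds_i`` (segment ``i`` joins point ``i`` to ``i+1``,
    cyclically)."""

    points: np.ndarray  # (n, 2) metres
    normals: np.ndarray  # (n, 2) outward unit vectors
    seg_lengths: np.ndarray  # (n,) metres
    t: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.seg_lengths = np.asarray(self.seg_lengths, dtype=float)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        return float(self.seg_lengths.sum())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourKinematics:
    """Per-point surface velocity, per-segment BSR and per-point BSV.

    ``bsr`` lives on segments (the angle is defined on the line segment
    joining adjacent control points); ``bsr_point`` is the mean of the
    two segments adjacent to each point, for point-wise subsetting.
    ``bsr_norm``/``bsv_norm`` are normalised by the per-frame maximum
    magnitude on the body, so they lie in [-1, 1].
    """

    u_body: np.ndarray  # (n, 2) m/s
    bsr: np.ndarray  # (n,) rad/s, per segment
    bsr_point: np.ndarray  # (n,) rad/s, per point
    bsv: np.ndarray | None = None  # (n,) 1/s
    bsv_valid: np.ndarray | None = None  # (n,) bool

    @property
    def bsr_norm(self) -> np.ndarray:
        m = np.max(np.abs(self.bsr))
        return self.bsr / m if m > 0 else np.zeros_like(self.bsr)

    @property
    def bsv_norm(self) -> np.ndarray:
        if self.bsv is None:
            raise DataError("bsv not computed")
        vals = np.where(self.bsv_valid, self.bsv, np.nan)
        m = np.nanmax(np.abs(vals))
        out = vals / m if m > 0 else np.zeros_like(vals)
        return out


@dataclass(frozen=True)
class SwimFrame:
    """Swimming direction, transverse unit vector and mean speed."""

    s_hat: tuple[float, float]
    j_hat: tuple[float, float]
    U: float
    U_bl: float
    body_length: float

    @property
    def s(self) -> np.ndarray:
        return np.array(self.s_hat)

    @property
    def j(self) -> np.ndarray:
        return np.array(self.j_hat)


@dataclass
class VorticityFrame:
    """Out-of-plane vorticity omega = dv/dx - du/dy on the grid; valid
    only where the central stencil touches only valid velocity nodes."""

    grid: Grid2D
    t: float
    omega: np.ndarray
    valid: np.ndarray


# ---------------------------------------------------------------------------


def extract_contour(mask: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Trace the body boundary from a binary raster at sub-cell precision.

    Returns an open-stored, logically closed counterclockwise polyline of
    (x, y) vertices in metres, obtained as the 0.5 iso-contour of the 0/1
    raster. The mask must contain exactly one connected component of at
    least 20 cells, not touching the domain edge.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise DataError(f"mask/grid shape mismatch: {mask.shape} vs {grid.shape}")
    labels, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise DataError(f"ambiguous body: {n_comp} connected components")
    if mask.sum() < 20:
        raise DataError(f"ambiguous body: component has only {int(mask.sum())} cells")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise DataError("body clipped: mask touches the domain edge")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DataError("ambiguous body: no iso-contour found")
    rc = max(contours, key=len)  # outer boundary (longest); holes ignored
    if np.linalg.norm(rc[0] - rc[-1]) > 1e-12:
        raise DataError("body clipped: open boundary contour")
    rc = rc[:-1]
    xy = np.column_stack(
        [grid.origin[0] + rc[:, 1] * grid.dx, grid.origin[1] + rc[:, 0] * grid.dy]
    )
    # enforce counterclockwise orientation
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        xy = xy[::-1]
    return xy


def resample_contour(
    polyline: np.ndarray,
    n: int = 60,
    s_hat: Sequence[float] | None = None,
    t: float = 0.0,
) -> BodyContour:
    """Resample a closed polyline to ``n`` control points equally spaced
    in arc length.

    Point 0 is anchored at the most-anterior vertex: the vertex with
    maximal projection on ``s_hat`` (max-x when no swimming direction is
    known yet). Normals come from adjacent-point tangents and point
    outward for the counterclockwise orientation.
    """
    pl = np.asarray(polyline, dtype=float)
    if len(pl) >= 2 and np.linalg.norm(pl[0] - pl[-1]) < 1e-15:
        pl = pl[:-1]
    if len(pl) < 4:
        raise DataError("contour polyline needs >= 4 vertices")
    seg = np.linalg.norm(np.diff(np.vstack([pl, pl[:1]]), axis=0), axis=1)
    if seg.sum() <= 0:
        raise DataError("degenerate (zero-length) contour polyline")
    anchor_dir = np.array([1.0, 0.0]) if s_hat is None else np.asarray(s_hat, float)
    k0 = int(np.argmax(pl @ anchor_dir))
    pl = np.roll(pl, -k0, axis=0)

    closed = np.vstack([pl, pl[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(chord)])
    S = s[-1]
    targets = np.arange(n) * (S / n)
    px = np.interp(targets, s, closed[:, 0])
    py = np.interp(targets, s, closed[:, 1])
    pts = np.column_stack([px, py])

    tangents = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tn = np.linalg.norm(tangents, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    tangents = tangents / tn
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])  # outward for CCW
    ds = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    return BodyContour(points=pts, normals=normals, seg_lengths=ds, t=t)


def _segment_angles(c: BodyContour) -> np.ndarray:
    d = np.roll(c.points, -1, axis=0) - c.points
    return np.arctan2(d[:, 1], d[:, 0])


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-pi, pi] (minimal-change unwrapping)."""
    return (a + np.pi) % (2 * np.pi) - np.pi


def surface_kinematics(
    prev: BodyContour, curr: BodyContour, nxt: BodyContour, dt: float | None = None
) -> ContourKinematics:
    """Surface velocity and BSR at ``curr`` by central differences over a
    (prev, curr, next) contour triple.

    The segment angle is measured in the lab frame with ``atan2``; its
    rate of change uses minimal-change unwrapping (jumps beyond pi are
    folded back by 2*pi).
    """
    if not (prev.n == curr.n == nxt.n):
        raise DataError("contour point counts differ across frames")
    if dt is None:
        dt = (nxt.t - prev.t) / 2.0
    if dt <= 0:
        raise DataError("dt must be positive")
    u_body = (nxt.points - prev.points) / (2.0 * dt)
    th_p = _segment_angles(prev)
    th_n = _segment_angles(nxt)
    bsr = _wrap(th_n - th_p) / (2.0 * dt)
    bsr_point = 0.5 * (np.roll(bsr, 1) + bsr)
    return ContourKinematics(u_body=u_body, bsr=bsr, bsr_point=bsr_point)


def vorticity_field(frame: VelocityFrame) -> VorticityFrame:
    """omega = dv/dx - du/dy by second-order central differences.

    Nodes whose stencil touches an invalid or out-of-domain node are
    marked invalid rather than evaluated one-sided.
    """
    g = frame.grid
    u, v = frame.u, frame.v
    omega = np.full(g.shape, np.nan)
    omega[1:-1, 1:-1] = (v[1:-1, 2:] - v[1:-1, :-2]) / (2 * g.dx) - (
        u[2:, 1:-1] - u[:-2, 1:-1]
    ) / (2 * g.dy)
    valid = ndimage.binary_erosion(frame.valid, structure=_CROSS, border_value=0)
    valid &= np.isfinite(omega)
    return VorticityFrame(grid=g, t=frame.t, omega=omega, valid=valid)


def body_surface_vorticity(
    contour: BodyContour, omega: VorticityFrame, max_cells: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fluid vorticity at the valid node nearest each control point.

    The nearest-node search is Euclidean, capped at ``max_cells`` grid
    cells; unreachable points are flagged invalid and return NaN.
    """
    g = omega.grid
    bsv = np.full(contour.n, np.nan)
    ok = np.zeros(contour.n, dtype=bool)
    reach = int(np.ceil(max_cells)) + 1
    for k, (x, y) in enumerate(contour.points):
        j0 = int(round((x - g.origin[0]) / g.dx))
        i0 = int(round((y - g.origin[1]) / g.dy))
        i_lo, i_hi = max(i0 - reach, 0), min(i0 + reach + 1, g.ny)
        j_lo, j_hi = max(j0 - reach, 0), min(j0 + reach + 1, g.nx)
        sub = omega.valid[i_lo:i_hi, j_lo:j_hi]
        if not sub.any():
            continue
        ii, jj = np.nonzero(sub)
        xi = g.origin[0] + (jj + j_lo) * g.dx
        yi = g.origin[1] + (ii + i_lo) * g.dy
        d2 = ((xi - x) / g.dx) ** 2 + ((yi - y) / g.dy) ** 2
        kmin = int(np.argmin(d2))
        if d2[kmin] > max_cells**2:
            continue
        bsv[k] = omega.omega[ii[kmin] + i_lo, jj[kmin] + j_lo]
        ok[k] = True
    return bsv, ok


def swim_frame(
    contours: Sequence[BodyContour],
    mode: str = "auto",
    fixed_vector: Sequence[float] | None = None,
    min_displacement: float = 1e-9,
) -> SwimFrame:
    """Swimming direction and mean speed from the centroid trajectory.

    ``s_hat`` is the least-squares line through the per-frame centroids
    (principal direction), oriented along the net displacement; ``U`` is
    the net centroid displacement projected on ``s_hat`` divided by the
    elapsed time. ``j_hat`` is ``s_hat`` rotated +90 degrees. Body length
    is the mean extent of the contour along ``s_hat``.
    """
    if len(contours) < 3:
        raise DataError(">=3 contour frames required for the swim frame")
    cents = np.array([c.centroid() for c in contours])
    disp = cents[-1] - cents[0]
    elapsed = contours[-1].t - contours[0].t
    if elapsed <= 0:
        raise DataError("contour times must increase")
    if mode == "fixed":
        if fixed_vector is None:
            raise DataError("fixed mode needs a direction vector")
        s = np.asarray(fixed_vector, float)
        s = s / np.linalg.norm(s)
    else:
        if np.linalg.norm(disp) < min_displacement:
            raise NumericalError("stationary body: direction undefined")
        dc = cents - cents.mean(axis=0)
        _, _, vt = np.linalg.svd(dc, full_matrices=False)
        s = vt[0]
        if np.dot(s, disp) < 0:
            s = -s
    U = max(float(np.dot(disp, s)) / elapsed, 0.0)
    j = np.array([-s[1], s[0]])
    proj = [c.points @ s for c in contours]
    L = float(np.mean([p.max() - p.min() for p in proj]))
    return SwimFrame(
        s_hat=(float(s[0]), float(s[1])),
        j_hat=(float(j[0]), float(j[1])),
        U=U,
        U_bl=U / L if L > 0 else float("nan"),
        body_length=L,
    )
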