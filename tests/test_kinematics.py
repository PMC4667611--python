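"""Contour extraction, resampling, BSR/BSV and the swim frame."""

import numpy as np
import pytest

from pullpush import (
    BodyContour,
    DataError,
    Grid2D,
    NumericalError,
    VelocityFrame,
    VorticityFrame,
    body_surface_vorticity,
    extract_contour,
    resample_contour,
    surface_kinematics,
    swim_frame,
    vorticity_field,
)

from conftest import make_swimmer


def circle_polyline(R=1.0, center=(0.0, 0.0), m=720):
    th = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)])


def grid_unit(n=64, d=1.0):
    return Grid2D(nx=n, ny=n, dx=d / (n - 1), dy=d / (n - 1))


class TestExtractContour:
    def test_square_perimeter(self):
        grid = Grid2D(nx=40, ny=40, dx=1.0, dy=1.0)
        m = np.zeros(grid.shape, bool)
        m[10:20, 12:22] = True  # 10x10 cells
        poly = extract_contour(m, grid)
        per = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1).sum()
        assert per == pytest.approx(40.0, rel=0.05)

    def test_disk_boundary_radius(self):
        grid = Grid2D(nx=101, ny=101, dx=1.0, dy=1.0)
        X, Y = grid.mesh()
        R = 20.0
        m = (X - 50) ** 2 + (Y - 50) ** 2 < R**2
        poly = extract_contour(m, grid)
        r = np.hypot(poly[:, 0] - 50, poly[:, 1] - 50)
        assert np.all(np.abs(r - R) < 0.7)

    def test_errors(self):
        grid = Grid2D(nx=40, ny=40, dx=1.0, dy=1.0)
        m = np.zeros(grid.shape, bool)
        m[5:12, 5:12] = True
        m[25:32, 25:32] = True
        with pytest.raises(DataError, match="ambiguous body"):
            extract_contour(m, grid)
        m2 = np.zeros(grid.shape, bool)
        m2[0:10, 5:12] = True  # touches the edge
        with pytest.raises(DataError, match="body clipped"):
            extract_contour(m2, grid)


class TestResampleContour:
    def test_circle_default_sixty_equal_points(self):
        c = resample_contour(circle_polyline())
        assert c.n == 60
        spacing = np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points, axis=1)
        np.testing.assert_allclose(spacing, spacing[0], rtol=1e-6)
        # outward normals on a circle point radially
        rad = c.points / np.linalg.norm(c.points, axis=1, keepdims=True)
        assert np.all(np.sum(rad * c.normals, axis=1) > 0.99)

    def test_square_n8_hits_corners_and_midpoints(self):
        sq = np.array([[1, -1], [1, 1], [-1, 1], [-1, -1]], dtype=float)
        dense = []
        for a, b in zip(sq, np.roll(sq, -1, axis=0)):
            for f in np.linspace(0, 1, 50, endpoint=False):
                dense.append(a + f * (b - a))
        c = resample_contour(np.array(dense), n=8)
        expected = {(1, -1), (1, 1), (-1, 1), (-1, -1), (1, 0), (0, 1), (-1, 0), (0, -1)}
        got = {tuple(np.round(p, 6)) for p in c.points}
        assert got == expected

    def test_idempotent_on_equally_spaced_contour(self):
        c1 = resample_contour(circle_polyline(R=0.5, m=600))
        c2 = resample_contour(c1.points)
        np.testing.assert_allclose(c2.points, c1.points, rtol=0, atol=1e-9 * 0.5)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(DataError):
            resample_contour(np.zeros((6, 2)))


class TestSurfaceKinematics:
    def test_rigid_rotation_bsr_equals_omega(self):
        omega, dt = 1.0, 1e-4
        base = resample_contour(circle_polyline(R=0.3, center=(0.1, 0.2)))

        def rot(c, ang):
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            ctr = np.array([0.1, 0.2])
            return BodyContour((c.points - ctr) @ R.T + ctr, c.normals @ R.T,
                               c.seg_lengths, t=ang / omega)

        kin = surface_kinematics(rot(base, -omega * dt), base, rot(base, omega * dt), dt)
        np.testing.assert_allclose(kin.bsr, omega, atol=1e-3)

    def test_pure_translation(self):
        v = np.array([0.3, -0.1])
        dt = 0.01
        base = resample_contour(circle_polyline(R=0.2))

        def shift(s):
            return BodyContour(base.points + s * v, base.normals, base.seg_lengths, t=s)

        kin = surface_kinematics(shift(-dt), shift(0.0), shift(dt), dt)
        np.testing.assert_allclose(kin.bsr, 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.u_body, np.tile(v, (60, 1)), atol=1e-12)

    def test_traveling_wave_bsr_crest_advances_at_phase_speed(self):
        ds = make_swimmer("traveling", n_frames=6)
        p = ds.params
        dt = 0.02
        crest_x = []
        for k in range(1, 5):
            kin = surface_kinematics(ds.contours[k - 1], ds.contours[k],
                                     ds.contours[k + 1], dt)
            # track the BSR crest on the upper side (first half of points),
            # in the body frame (remove the swimming translation)
            half = slice(1, 28)
            i = np.argmax(kin.bsr[half]) + 1
            mid = 0.5 * (ds.contours[k].points[i] + ds.contours[k].points[i + 1])
            crest_x.append(mid[0] + p.U * ds.contours[k].t)
        speeds = np.diff(crest_x) / dt
        c_wave = p.lam / p.T_p
        ds_pt = np.mean(ds.contours[1].seg_lengths)
        assert np.all(np.abs(np.array(speeds) - c_wave) <= ds_pt / dt + 1e-9)


class TestVorticity:
    def test_solid_body_rotation_twice_omega_exact(self):
        grid = grid_unit(32)
        X, Y = grid.mesh()
        om = 1.0
        f = VelocityFrame(grid, 0.0, -om * (Y - 0.5), om * (X - 0.5))
        vf = vorticity_field(f)
        np.testing.assert_allclose(vf.omega[vf.valid], 2.0 * om, atol=1e-12)

    def test_plane_shear_exact(self):
        grid = grid_unit(32)
        X, Y = grid.mesh()
        f = VelocityFrame(grid, 0.0, 3.0 * Y, np.zeros_like(X))
        vf = vorticity_field(f)
        np.testing.assert_allclose(vf.omega[vf.valid], -3.0, atol=1e-12)

    def test_affine_field_exact_and_boundary_invalid(self):
        grid = grid_unit(16)
        X, Y = grid.mesh()
        f = VelocityFrame(grid, 0.0, 0.3 + 1.1 * X - 0.7 * Y, -0.2 + 0.5 * X + 0.9 * Y)
        vf = vorticity_field(f)
        np.testing.assert_allclose(vf.omega[vf.valid], 0.5 + 0.7, atol=1e-12)
        assert not vf.valid[0].any() and not vf.valid[:, -1].any()

    def test_irrotational_flow_small_vorticity(self, cylinder):
        case = cylinder["case"]
        vf = vorticity_field(case.velocity[0])
        grid = case.velocity.grid
        X, Y = grid.mesh()
        far = np.hypot(X, Y) > 2 * cylinder["R"]
        ok = vf.valid & far
        # truncation-level only: |omega| <= C dx^2 scale
        assert np.max(np.abs(vf.omega[ok])) < 0.05 * 0.1 / cylinder["R"]


class TestBodySurfaceVorticity:
    def test_uniform_field_lookup(self):
        grid = grid_unit(32)
        vf = VorticityFrame(grid, 0.0, np.full(grid.shape, 5.0), np.ones(grid.shape, bool))
        c = resample_contour(circle_polyline(R=0.3, center=(0.5, 0.5)))
        bsv, ok = body_surface_vorticity(c, vf)
        assert ok.all()
        np.testing.assert_allclose(bsv, 5.0)

    def test_unreachable_points_flagged(self):
        grid = grid_unit(32)
        vf = VorticityFrame(grid, 0.0, np.full(grid.shape, 5.0), np.zeros(grid.shape, bool))
        c = resample_contour(circle_polyline(R=0.3, center=(0.5, 0.5)))
        bsv, ok = body_surface_vorticity(c, vf)
        assert not ok.any()
        assert np.all(np.isnan(bsv))

    def test_nearest_node_closed_form(self):
        # closed-form Lamb-Oseen vorticity placed on the grid; the lookup
        # must return exactly the nearest valid node's value
        grid = grid_unit(64)
        X, Y = grid.mesh()
        Gamma, rc = 0.01, 0.1
        r2 = (X - 0.5) ** 2 + (Y - 0.5) ** 2
        om = Gamma / (np.pi * rc**2) * np.exp(-r2 / rc**2)
        vf = VorticityFrame(grid, 0.0, om, np.ones(grid.shape, bool))
        c = resample_contour(circle_polyline(R=0.2, center=(0.5, 0.5), m=240), n=12)
        bsv, ok = body_surface_vorticity(c, vf)
        assert ok.all()
        for k, pt in enumerate(c.points):
            i = int(round((pt[1] - grid.origin[1]) / grid.dy))
            j = int(round((pt[0] - grid.origin[0]) / grid.dx))
            assert bsv[k] == om[i, j]


class TestSwimFrame:
    def _translating_contours(self, vel, n_frames=5, dt=0.1):
        base = circle_polyline(R=0.05, m=300)
        out = []
        for k in range(n_frames):
            t = k * dt
            out.append(resample_contour(base + np.asarray(vel) * t, t=t))
        return out

    def test_translating_centroid(self):
        sw = swim_frame(self._translating_contours((0.24, 0.0)))
        assert sw.s_hat == pytest.approx((1.0, 0.0), abs=1e-9)
        assert sw.U == pytest.approx(0.24, rel=1e-9)
        assert sw.j_hat == pytest.approx((0.0, 1.0), abs=1e-9)

    def test_stationary_body_raises(self):
        with pytest.raises(NumericalError, match="direction undefined"):
            swim_frame(self._translating_contours((0.0, 0.0)))

    def test_fixed_mode_overrides(self):
        sw = swim_frame(self._translating_contours((0.0, 0.0)), mode="fixed",
                        fixed_vector=(0.0, 2.0))
        assert sw.s_hat == pytest.approx((0.0, 1.0))

    def test_swimmer_speed_self_consistency(self):
        ds = make_swimmer("traveling", n_frames=10)
        sw = swim_frame(ds.contours)
        assert sw.U_bl == pytest.approx(2.0, rel=0.15)
        assert sw.s_hat[0] == pytest.approx(-1.0, abs=0.05)


def test_no_slip_bsv_matches_bsr_sign(swimmer_pair):
    """Fluid adjacent to the surface rotates with the surface: the sign
    of BSV tracks the sign of BSR at >= 80% of points in traveling mode
    (ground-truth contours)."""
    ds = swimmer_pair["traveling"]["dataset"]
    match = []
    for k in range(1, len(ds.contours) - 1):
        kin = surface_kinematics(ds.contours[k - 1], ds.contours[k],
                                 ds.contours[k + 1], 0.02)
        vf = vorticity_field(ds.velocity[k])
        bsv, ok = body_surface_vorticity(ds.contours[k], vf)
        match.append(np.mean(np.sign(bsv[ok]) == np.sign(kin.bsr_point[ok])))
    assert np.mean(match) >= 0.80


def test_bsr_bsv_normalisation_bounds(swimmer_pair):
    ds = swimmer_pair["traveling"]["dataset"]
    kin = surface_kinematics(ds.contours[0], ds.contours[1], ds.contours[2], 0.02)
    vf = vorticity_field(ds.velocity[1])
    kin.bsv, kin.bsv_valid = body_surface_vorticity(ds.contours[1], vf)
    assert np.max(np.abs(kin.bsr_norm)) == 1.0
    assert np.nanmax(np.abs(kin.bsv_norm)) == 1.0
    assert np.all(np.abs(kin.bsr_norm) <= 1.0)
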