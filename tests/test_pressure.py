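"""The momentum-balance stages and the median-of-eight-path integrator."""

import numpy as np
import pytest

from pullpush import (
    AnalysisConfig,
    DataError,
    FluidProperties,
    Grid2D,
    NumericalError,
    VelocityFrame,
    VelocitySequence,
    integrate_pressure,
    material_acceleration,
    poisson_pressure_oracle,
    pressure_gradient,
    pressure_sequence,
)
from pullpush.pressure import PressureGradientField, eight_path_pressures, _edge_pressures
from pullpush.synthetic import taylor_green, taylor_green_grid

from conftest import TG_DT, TG_NU, TG_RHO, rel_l2_mean_removed, solve_tg_pressure


def unit_grid(n=64):
    h = 1.0 / (n - 1)
    return Grid2D(nx=n, ny=n, dx=h, dy=h)


def steady_seq(grid, u, v, n=3, dt=0.1):
    return VelocitySequence([VelocityFrame(grid, k * dt, u, v) for k in range(n)])


class TestMaterialAcceleration:
    def test_steady_uniform_flow_zero(self):
        grid = unit_grid(16)
        seq = steady_seq(grid, np.full(grid.shape, 0.1), np.zeros(grid.shape))
        acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
        np.testing.assert_allclose(acc.ax[acc.valid], 0.0, atol=1e-14)
        np.testing.assert_allclose(acc.ay[acc.valid], 0.0, atol=1e-14)

    def test_solid_body_rotation_centripetal(self):
        # steady rotation: Du/Dt = -Omega^2 r r_hat; at r=0.02, |a|=0.02
        grid = Grid2D(nx=41, ny=41, dx=0.002, dy=0.002, origin=(-0.04, -0.04))
        X, Y = grid.mesh()
        om = 1.0
        seq = steady_seq(grid, -om * Y, om * X)
        acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
        i, j = 20, 30  # (x, y) = (0.02, 0)
        assert acc.ax[i, j] == pytest.approx(-0.02, rel=1e-9)
        assert acc.ay[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_taylor_green_matches_closed_form(self):
        errs = []
        for n in (65, 129):
            case = taylor_green(taylor_green_grid(n), rho=1.0, nu=0.0,
                                times=(0.0, 0.1, 0.2))
            seq = case.velocity
            acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
            X, Y = seq.grid.mesh()
            # analytic Du/Dt at nu=0: (sin 2x, sin 2y)/2
            ax_true = 0.5 * np.sin(2 * X)
            ay_true = 0.5 * np.sin(2 * Y)
            errs.append(np.max(np.abs(acc.ax - ax_true)[acc.valid]))
            assert np.max(np.abs(acc.ay - ay_true)[acc.valid]) < 4 * errs[-1] + 1e-12
        assert errs[1] < errs[0] * 0.35  # ~O(dx^2)

    def test_bad_dt_rejected(self):
        grid = unit_grid(8)
        seq = steady_seq(grid, np.zeros(grid.shape), np.zeros(grid.shape))
        with pytest.raises(DataError, match="dt"):
            material_acceleration(seq[0], seq[1], seq[2], dt=0.0)


class TestPressureGradient:
    def test_quiescent_fluid_zero(self):
        grid = unit_grid(16)
        seq = steady_seq(grid, np.zeros(grid.shape), np.zeros(grid.shape))
        acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
        grad = pressure_gradient(acc, seq[1], FluidProperties(rho=1000.0, mu=1e-3))
        np.testing.assert_allclose(grad.gx[grad.valid], 0.0, atol=1e-14)

    def test_poiseuille_exact(self):
        # u = U0 (1 - (y/h)^2), gx = -2 mu U0 / h^2 = -2.0 Pa/m
        U0, hchan, mu = 0.1, 0.01, 1e-3
        grid = Grid2D(nx=21, ny=21, dx=0.001, dy=0.001, origin=(0.0, -0.01))
        X, Y = grid.mesh()
        u = U0 * (1 - (Y / hchan) ** 2)
        seq = steady_seq(grid, u, np.zeros_like(u))
        acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
        grad = pressure_gradient(acc, seq[1], FluidProperties(rho=1000.0, mu=mu))
        np.testing.assert_allclose(grad.gx[grad.valid], -2.0, rtol=1e-9)
        np.testing.assert_allclose(grad.gy[grad.valid], 0.0, atol=1e-9)

    def test_taylor_green_gradient_second_order(self):
        errs = []
        for n in (65, 129):
            case = taylor_green(taylor_green_grid(n), rho=TG_RHO, nu=TG_NU,
                                times=np.arange(3) * TG_DT)
            seq = case.velocity
            acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
            grad = pressure_gradient(acc, seq[1], FluidProperties(TG_RHO, TG_RHO * TG_NU))
            X, Y = seq.grid.mesh()
            F2 = np.exp(-2 * TG_NU * seq[1].t) ** 2
            gx_true = -0.5 * TG_RHO * np.sin(2 * X) * F2
            errs.append(np.max(np.abs(grad.gx - gx_true)[grad.valid]) / (0.5 * TG_RHO))
        assert errs[1] < errs[0] * 0.35


def gaussian_bump_gradient(n=128, sigma=0.12):
    grid = unit_grid(n)
    X, Y = grid.mesh()
    p = np.exp(-((X - 0.5) ** 2 + (Y - 0.5) ** 2) / (2 * sigma**2))
    gy, gx = np.gradient(p, grid.dy, grid.dx, edge_order=2)
    return grid, p, PressureGradientField(grid, 0.0, gx, gy, np.ones(grid.shape, bool))


class TestIntegratePressure:
    def test_zero_gradient_gives_zero_everywhere(self):
        grid = unit_grid(32)
        grad = PressureGradientField(grid, 0.0, np.zeros(grid.shape),
                                     np.zeros(grid.shape), np.ones(grid.shape, bool))
        pf = integrate_pressure(grad)
        np.testing.assert_allclose(pf.p, 0.0, atol=1e-12)
        assert np.all(pf.n_paths_used == 8)

    def test_gaussian_bump_reconstruction(self):
        # reconstruction from the central-difference gradient carries an
        # intrinsic O(dx^2) limit ~1.6e-3 at this resolution
        grid, p_true, grad = gaussian_bump_gradient()
        pf = integrate_pressure(grad)
        d = pf.p - p_true
        assert np.max(np.abs(d - d.mean())) <= 2e-3 * p_true.max()

    def test_fully_shadowed_node_flagged_and_filled(self):
        grid = unit_grid(33)
        valid = np.ones(grid.shape, bool)
        valid[14:20, 14:20] = False
        valid[16, 16] = True  # enclosed pocket: every ray crosses the ring
        grad = PressureGradientField(grid, 0.0, np.ones(grid.shape),
                                     np.zeros(grid.shape), valid)
        pf = integrate_pressure(grad)
        assert pf.n_paths_used[16, 16] == 0
        assert not pf.valid[16, 16]
        assert pf.interpolated[16, 16]
        assert np.isfinite(pf.p[16, 16])

    def test_all_invalid_rejected(self):
        grid = unit_grid(16)
        grad = PressureGradientField(grid, 0.0, np.zeros(grid.shape),
                                     np.zeros(grid.shape), np.zeros(grid.shape, bool))
        with pytest.raises(NumericalError, match="no computable nodes"):
            integrate_pressure(grad)

    def test_median_robust_to_single_ray_outlier(self):
        """With >= 5 agreeing rays, corrupting one ray's integrand leaves
        the median exactly untouched."""
        grid = unit_grid(33)
        grad = PressureGradientField(grid, 0.0, np.zeros(grid.shape),
                                     np.zeros(grid.shape), np.ones(grid.shape, bool))
        edge = _edge_pressures(grad.gx, grad.gy, grad.valid, grid, "ambient")
        stack = eight_path_pressures(grad, edge)
        clean = np.nanmedian(stack, axis=0)
        corrupted = stack.copy()
        corrupted[3, 16, 16] += 1e6  # one ray, one node
        new = np.nanmedian(corrupted, axis=0)
        assert new[16, 16] == clean[16, 16]

    def test_taylor_green_accuracy(self, tg128):
        err = rel_l2_mean_removed(tg128["pressure"].p, tg128["case"].pressure_truth[2].p,
                                  tg128["pressure"].valid)
        assert err <= 0.02


class TestPoissonOracle:
    def test_zero_gradient(self):
        grid = unit_grid(16)
        grad = PressureGradientField(grid, 0.0, np.zeros(grid.shape),
                                     np.zeros(grid.shape), np.ones(grid.shape, bool))
        pf = poisson_pressure_oracle(grad, bc="dirichlet")
        np.testing.assert_allclose(pf.p, 0.0, atol=1e-10)

    def test_gaussian_bump(self):
        grid, p_true, grad = gaussian_bump_gradient()
        pf = poisson_pressure_oracle(grad, bc="dirichlet")
        d = pf.p - p_true
        assert np.max(np.abs(d - d.mean())) <= 2e-3 * p_true.max()

    def test_agreement_with_path_integration_on_taylor_green(self, tg128):
        po = poisson_pressure_oracle(tg128["grad"], bc="neumann")
        pf = tg128["pressure"]
        both = pf.valid & po.valid
        d = (pf.p - pf.p[both].mean()) - (po.p - po.p[both].mean())
        rng = np.ptp(tg128["case"].pressure_truth[2].p)
        assert np.max(np.abs(d[both])) <= 0.02 * rng


class TestPressureSequence:
    def test_three_identical_steady_frames(self):
        grid = unit_grid(32)
        X, Y = grid.mesh()
        seq = steady_seq(grid, -Y + 0.5, X - 0.5)  # solid-body rotation
        out = pressure_sequence(seq, None, FluidProperties(rho=1000.0, mu=0.0))
        assert len(out) == 1
        # suction core at the rotation center
        assert out[0].p[16, 16] == pytest.approx(out[0].p.min())

    def test_two_frames_rejected(self):
        grid = unit_grid(8)
        seq = steady_seq(grid, np.zeros(grid.shape), np.zeros(grid.shape), n=2)
        with pytest.raises(DataError, match="3 frames required"):
            pressure_sequence(seq, None, FluidProperties())

    def test_convergence_order(self):
        errs = []
        for n in (32, 64, 128):
            case, pf, _ = solve_tg_pressure(n)
            errs.append(rel_l2_mean_removed(pf.p, case.pressure_truth[2].p, pf.valid))
        slopes = np.diff(np.log(errs)) / np.diff(np.log([1 / 31, 1 / 63, 1 / 127]))
        assert np.all((slopes >= 1.6) & (slopes <= 2.4))
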