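"""Shared fixtures: solved analytic cases and swimmer pipeline runs.

Everything is generated programmatically; the heavier objects are
session-scoped so the analytic solves and the two swimmer pipeline runs
happen once.
"""

import numpy as np
import pytest

from pullpush import (
    AnalysisConfig,
    FluidProperties,
    Grid2D,
    analyze,
    integrate_pressure,
    material_acceleration,
    pressure_gradient,
)
from pullpush.synthetic import (
    SwimmerParams,
    potential_cylinder,
    swimmer_grid,
    synth_swimmer,
    taylor_green,
    taylor_green_grid,
)

TG_RHO = 1000.0
TG_NU = 1e-6
TG_DT = 0.2  # the flow's advective timescale is ~1 s; quasi-steady in time


def solve_tg_pressure(n, config=None):
    """Taylor-Green case at resolution n plus its recovered mid-frame
    pressure; returns (case, PressureFrame)."""
    case = taylor_green(taylor_green_grid(n), rho=TG_RHO, nu=TG_NU,
                        times=np.arange(5) * TG_DT)
    seq = case.velocity
    fluid = FluidProperties(rho=TG_RHO, mu=TG_RHO * TG_NU)
    acc = material_acceleration(seq[1], seq[2], seq[3], seq.dt)
    grad = pressure_gradient(acc, seq[2], fluid)
    return case, integrate_pressure(grad, config=config), grad


def rel_l2_mean_removed(p, truth, valid):
    """Relative L2 error after removing the mean over valid nodes."""
    d = (p - p[valid].mean()) - (truth - truth[valid].mean())
    ref = truth - truth[valid].mean()
    return float(np.linalg.norm(d[valid]) / np.linalg.norm(ref[valid]))


@pytest.fixture(scope="session")
def tg128():
    case, pf, grad = solve_tg_pressure(128)
    return {"case": case, "pressure": pf, "grad": grad}


@pytest.fixture(scope="session")
def cylinder():
    """Potential flow past a cylinder, R ~ 80 cells on a 320^2 grid, with
    the recovered pressure field."""
    R = 0.02
    n = 320
    h = 4 * R / (n - 1)
    grid = Grid2D(nx=n, ny=n, dx=h, dy=h, origin=(-2 * R, -2 * R))
    case = potential_cylinder(grid, U_inf=0.1, R=R, rho=1000.0)
    seq = case.velocity
    acc = material_acceleration(seq[0], seq[1], seq[2], seq.dt)
    grad = pressure_gradient(acc, seq[1], FluidProperties(rho=1000.0, mu=0.0),
                             include_viscous=False)
    pf = integrate_pressure(grad, mask=case.mask[1])
    return {"case": case, "pressure": pf, "grad": grad, "R": R, "U": 0.1, "rho": 1000.0}


def make_swimmer(mode, n_frames=22, dt=0.02, seed=0):
    params = SwimmerParams(wave_mode=mode, n_frames=n_frames, seed=seed)
    grid = swimmer_grid(params, dt)
    return synth_swimmer(params, grid, dt)


@pytest.fixture(scope="session")
def swimmer_pair():
    """Traveling and standing swimmer datasets (same seed) plus their
    full pipeline reports over one wave cycle."""
    out = {}
    for mode in ("traveling", "standing"):
        ds = make_swimmer(mode)
        cfg = AnalysisConfig(rng_seed=0, cycle_bounds=(0.02, 0.42))
        out[mode] = {"dataset": ds, "report": analyze(ds.velocity, ds.masks, cfg)}
    return out
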