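"""Lateral power and the pull/push hydrodynamic efficiencies.

A Froude-type efficiency compares the useful power T*U (time-averaged
gross forward thrust times mean swimming speed) with the power lost to
lateral motions of the body,

    eta = T U / (T U + P_lat),

where the lateral power at one instant sums, over surface elements,

    w_i = p_i (n_hat_i . j_hat) (u_body_i . j_hat) dA_i,

the rate of work done by the body on the fluid transverse to the
swimming direction (j_hat). Restricting both the thrust and the lateral
power to the low-pressure (pull) elements gives the efficiency of the
suction mechanism alone,

    eta_pull = T_pull U / (T_pull U + P_lat,pull),

and eta_push analogously for the high-pressure elements. Subset
membership is evaluated per element per frame; the signed integral is
used as-is (negative local terms represent genuine energy recovery), so
a negative cycle-averaged P_lat is reported unclamped and flagged rather
than silently rectified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NumericalError
from .forces import CycleForceSummary, ForceDecomposition, SurfacePressure, element_areas
from .kinematics import BodyContour, ContourKinematics, SwimFrame

__all__ = [
    "EfficiencyReport",
    "lateral_power",
    "hydrodynamic_efficiency",
    "partition_efficiencies",
]


@dataclass
class EfficiencyReport:
    """Cycle-averaged thrust, lateral power and efficiencies.

    Efficiencies lie in [0, 1] whenever their thrust, speed and lateral
    power inputs are non-negative; ``None`` marks an undefined ratio
    (no hydrodynamic work in that subset). ``flags`` records anomalies
    such as negative cycle-averaged lateral power.
    """

    window: tuple[float, float]
    U: float
    T: float
    T_pull: float
    T_push: float
    P_lat: float
    P_lat_pull: float
    P_lat_push: float
    eta: float | None
    eta_pull: float | None
    eta_push: float | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "U": self.U,
            "T": self.T,
            "T_pull": self.T_pull,
            "T_push": self.T_push,
            "P_lat": self.P_lat,
            "P_lat_pull": self.P_lat_pull,
            "P_lat_push": self.P_lat_push,
            "eta": self.eta,
            "eta_pull": self.eta_pull,
            "eta_push": self.eta_push,
            "flags": list(self.flags),
        }


def lateral_power(
    sample: SurfacePressure,
    kin: ContourKinematics,
    contour: BodyContour,
    frame: SwimFrame,
    subset: str = "all",
    mode: str = "planar",
    axis=None,
    dead_band: float = 0.0,
) -> float:
    """Instantaneous lateral power, W/m (planar) or W (axisymmetric).

    ``subset`` selects all elements, the low-pressure (pull) elements
    (p < -dead_band) or the high-pressure (push) elements; per-frame
    subset sums are exactly additive: pull + push + neutral = all.
    """
    dA = element_areas(contour, mode=mode, axis=axis)
    j = frame.j
    n_j = contour.normals @ j
    ub_j = kin.u_body @ j
    w = np.where(sample.resolved, sample.p, 0.0) * n_j * ub_j * dA
    if subset == "all":
        sel = sample.resolved
    elif subset == "pull":
        sel = sample.resolved & (sample.p < -dead_band)
    elif subset == "push":
        sel = sample.resolved & (sample.p > dead_band)
    else:
        raise DataError(f"unknown subset {subset!r}")
    return float(w[sel].sum())


def hydrodynamic_efficiency(T: float, U: float, P_lat: float) -> float:
    """eta = T U / (T U + P_lat).

    Limits: eta -> 1 with no lateral loss, 0.5 at equal split, 0 at zero
    thrust. A negative P_lat can push eta above 1; the value is returned
    as-is (callers flag it).
    """
    if U < 0 or T < 0:
        raise DataError("T and U must be non-negative")
    denom = T * U + P_lat
    if denom == 0:
        raise NumericalError("no hydrodynamic work: T*U + P_lat = 0")
    return T * U / denom


def partition_efficiencies(
    summary: CycleForceSummary,
    lat_series: dict[str, np.ndarray],
    times: np.ndarray,
    frame: SwimFrame,
) -> EfficiencyReport:
    """Assemble the full efficiency report over one averaging window.

    ``lat_series`` maps "all"/"pull"/"push" to per-frame lateral power
    arrays aligned with ``times`` (already restricted to the window).
    """
    times = np.asarray(times, float)

    def tmean(y):
        y = np.asarray(y, float)
        if len(y) == 1:
            return float(y[0])
        return float(np.trapezoid(y, times) / (times[-1] - times[0]))

    P_lat = tmean(lat_series["all"])
    P_pull = tmean(lat_series["pull"])
    P_push = tmean(lat_series["push"])
    T = summary.gross_thrust
    T_pull = summary.F_fpull
    T_push = summary.F_fpush
    U = frame.U
    flags = []
    for name, val in (("P_lat", P_lat), ("P_lat_pull", P_pull), ("P_lat_push", P_push)):
        if val < 0:
            flags.append(f"negative cycle-averaged {name}: eta may exceed 1")

    def eta_of(Tc, Pc):
        try:
            return hydrodynamic_efficiency(Tc, U, Pc)
        except NumericalError:
            return None

    return EfficiencyReport(
        window=summary.window,
        U=U,
        T=T,
        T_pull=T_pull,
        T_push=T_push,
        P_lat=P_lat,
        P_lat_pull=P_pull,
        P_lat_push=P_push,
        eta=eta_of(T, P_lat),
        eta_pull=eta_of(T_pull, P_pull),
        eta_push=eta_of(T_push, P_push),
        flags=flags,
    )
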