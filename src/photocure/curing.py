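"""Curing time/depth inversion, inhibition zone, steady-state time.

The film is cured at depth z once the accumulated exponent S(z, t)
exceeds the threshold S_T = ln(1/(1 - C_T)).  Because S is monotone in t
and non-increasing in z, the curing time T_C(z) and curing depth Z_C(t)
are inverse monotone maps of one another; both are computed by bracketed
root finding on the analytic S (authoritative), with the algebraic
inversion of the closed form retained as a cross-check.  The uncured
remainder Z_N = H - Z_C is the inhibition zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .efficacy import NO_CURE, induction_time, s_function, s_infinity
from .light import averaged_absorbance, initial_absorbance
from .params import ParamBundle, ParameterError
from .trajectory import Trajectory
from .viscosity import effective_K_correction

__all__ = [
    "CuringResult",
    "curing_time",
    "curing_depth",
    "steady_state_time",
    "inhibition_zone",
    "curing_depth_numeric",
    "compute_curing",
    "DEFAULT_S_T",
    "DEFAULT_C_T_NUMERIC",
]

#: analytic-layer threshold exponent (efficacy 0.86)
DEFAULT_S_T = 2.0
#: numeric-layer threshold efficacy
DEFAULT_C_T_NUMERIC = 0.8

_T_CAP = 1e9  # s; beyond this the film is considered uncurable


@dataclass
class CuringResult:
    """Curing depth curve and derived quantities for one parameter set."""

    C_T: float
    S_T: float
    t_grid: np.ndarray
    Z_C: np.ndarray                 # cm, per output time
    H: float
    T_S: float = NO_CURE            # steady-state time (Z_C >= 0.9 H)
    T_C_by_depth: dict = field(default_factory=dict)

    @property
    def Z_N(self) -> np.ndarray:
        return self.H - self.Z_C

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t_grid,
            "Z_C_um": self.Z_C * 1e4,
            "Z_N_um": self.Z_N * 1e4,
        })


def _analytic_t_ind(params: ParamBundle, z: float, include_oxygen: bool) -> float:
    if not include_oxygen or params.init.Y0 <= 0:
        return 0.0
    o = params.optics
    A2 = initial_absorbance(o, params.init.C0)
    B = o.b_exc * params.irr.I0 * params.init.C0 * math.exp(-A2 * z)
    return induction_time(1.0, params.init.Y0, params.rates.kp, B)


def curing_time(
    z: float,
    params: ParamBundle,
    method: str = "root",
    S_T: float = DEFAULT_S_T,
    include_oxygen: bool = False,
    use_a1: bool = False,
) -> float:
    """Smallest t with S(z, t) >= S_T; NO_CURE (inf) if unreachable.

    ``method="root"`` brackets and Brent-solves the monotone S (works for
    every model switch); ``"closed_form"`` algebraically inverts the
    A1 = 0 closed form and must satisfy S(T_C) = S_T.
    """
    if method not in ("root", "closed_form"):
        raise ParameterError(f"unknown curing_time method {method!r}")
    if z < -1e-15 or z > params.init.H * (1 + 1e-12):
        raise ParameterError("z outside [0, H]")
    z = min(max(z, 0.0), params.init.H)
    t_ind = _analytic_t_ind(params, z, include_oxygen)
    if not math.isfinite(t_ind):
        return NO_CURE

    if method == "closed_form":
        return _curing_time_closed(z, params, S_T, t_ind, use_a1)

    def f(t: float) -> float:
        return s_function(
            z, t, params, "closed_form",
            t_ind=t_ind, use_a1=use_a1,
        ) - S_T

    if not use_a1:
        S_inf = s_infinity(params, z)
        if params.viscosity.enabled and params.viscosity.m > 0:
            S_inf = S_inf * effective_K_correction(S_inf, params.viscosity.m)
        if S_inf < S_T:
            return NO_CURE
    hi = max(1.0, 2.0 * t_ind if t_ind > 0 else 1.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > _T_CAP:
            return NO_CURE
    lo = t_ind
    if f(lo) >= 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def _curing_time_closed(
    z: float, params: ParamBundle, S_T: float, t_ind: float, use_a1: bool
) -> float:
    """Algebraic inversion T_C = -(1/B'') ln(1 - S_T B''/D) + T_ID.

    D = K sqrt(0.5 b I0 C0 X) with X = exp(-A2 z); no cure when
    S_T B'' >= D (threshold above the steady-state exponent).  The
    viscosity K-correction makes the relation implicit in the
    *uncorrected* threshold S1; that scalar fixed point is solved first.
    """
    if use_a1:
        raise ParameterError(
            "closed-form inversion requires the frozen absorption (use_a1 off)"
        )
    o = params.optics
    init = params.init
    irr = params.irr
    A2 = initial_absorbance(o, init.C0)
    A_avg = averaged_absorbance(o, init.C0)
    X_att = math.exp(-A2 * z)
    B_pp = 0.5 * o.b_exc * irr.I0 * math.exp(-A_avg * z)
    D = params.K * math.sqrt(0.5 * o.b_exc * irr.I0 * init.C0 * X_att)
    if D <= 0 or B_pp <= 0:
        return NO_CURE

    S1_target = S_T
    if params.viscosity.enabled and params.viscosity.m > 0:
        m = params.viscosity.m

        def fixed(S1: float) -> float:
            return S1 * effective_K_correction(S1, m) - S_T

        hi = S_T / (1.0 - m) * 2.0
        if fixed(hi) < 0:
            return NO_CURE
        S1_target = float(brentq(fixed, S_T, hi, xtol=1e-14))

    arg = 1.0 - S1_target * B_pp / D
    if arg <= 0:
        return NO_CURE
    return t_ind - math.log(arg) / B_pp


def curing_depth(
    t: float,
    params: ParamBundle,
    method: str = "root",
    S_T: float = DEFAULT_S_T,
    include_oxygen: bool = False,
    use_a1: bool = False,
    z_tol: float = 1e-7,
) -> float:
    """Largest z in [0, H] with curing_time(z) <= t, by monotone bisection.

    Returns 0 if even the surface is uncured at t, H if the whole film is.
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    H = params.init.H

    def cured(z: float) -> bool:
        return curing_time(z, params, method, S_T, include_oxygen, use_a1) <= t

    if not cured(0.0):
        return 0.0
    if cured(H):
        return H
    lo, hi = 0.0, H
    while hi - lo > z_tol:
        mid = 0.5 * (lo + hi)
        if cured(mid):
            lo = mid
        else:
            hi = mid
    return lo


def steady_state_time(
    params: ParamBundle,
    fraction: float = 0.9,
    method: str = "root",
    S_T: float = DEFAULT_S_T,
    include_oxygen: bool = False,
    use_a1: bool = False,
) -> float:
    """First t with Z_C(t) >= fraction * H.

    Since T_C(z) is the exact inverse of the monotone Z_C(t), this equals
    the curing time at depth fraction * H.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must lie in (0, 1]")
    return curing_time(
        fraction * params.init.H, params, method, S_T, include_oxygen, use_a1
    )


def inhibition_zone(Z_C: float, H: float) -> float:
    """Uncured remainder Z_N = H - Z_C."""
    if Z_C < 0 or Z_C > H:
        raise ParameterError("Z_C must lie in [0, H]")
    return H - Z_C


def curing_depth_numeric(traj: Trajectory, C_T: float = DEFAULT_C_T_NUMERIC) -> np.ndarray:
    """Per-time curing depth of a simulated trajectory.

    For each output time, the deepest point whose linearly interpolated
    efficacy still reaches the threshold C_T.
    """
    if not (0 < C_T < 1):
        raise ParameterError("C_T must lie in (0, 1)")
    eff = traj.efficacy
    z = traj.z_grid
    nt = traj.t_grid.size
    out = np.zeros(nt)
    for j in range(nt):
        col = eff[:, j]
        if col[0] < C_T:
            out[j] = 0.0
            continue
        above = np.nonzero(col >= C_T)[0]
        i = above[-1]
        if i == z.size - 1:
            out[j] = z[-1]
        else:
            e0, e1 = col[i], col[i + 1]
            frac = (e0 - C_T) / (e0 - e1) if e1 < e0 else 0.0
            out[j] = z[i] + frac * (z[i + 1] - z[i])
    return out


def compute_curing(
    params: ParamBundle,
    t_grid: np.ndarray,
    method: str = "root",
    S_T: float = DEFAULT_S_T,
    C_T: float | None = None,
    include_oxygen: bool = False,
    use_a1: bool = False,
    ss_fraction: float = 0.9,
) -> CuringResult:
    """Full curing-depth analysis over a time grid (analytic layer)."""
    if C_T is None:
        C_T = 1.0 - math.exp(-S_T)
    t_grid = np.asarray(t_grid, dtype=float)
    Z_C = np.array([
        curing_depth(t, params, method, S_T, include_oxygen, use_a1)
        for t in t_grid
    ])
    T_S = steady_state_time(params, ss_fraction, method, S_T, include_oxygen, use_a1)
    return CuringResult(
        C_T=C_T, S_T=S_T, t_grid=t_grid, Z_C=Z_C, H=params.init.H, T_S=T_S
    )
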