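"""Quasi-steady-state kinetics.

Setting the time derivatives of the short-lived species (triplet T,
radicals R', R, singlet oxygen X) to zero turns the seven-species system
into algebra for the fast species plus three slow ODEs for the
photosensitizer C, dissolved oxygen O2 and monomer A.  Two tiers are
provided:

* ``"reduced3"`` -- the three-ODE reduction retaining the type-II
  (singlet-oxygen) channels and optional photosensitizer regeneration;
* ``"simplified"`` -- the working system used for the numeric figures:
  dC/dt = -b I C,  dO2/dt = -ki R O2 + P,  dA/dt = -kp R A,
  with the radical R from the closed-form quadratic root.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import light
from .params import ParamBundle, ParameterError
from .trajectory import Trajectory
from .viscosity import viscosity_scale

__all__ = [
    "QssaFactors",
    "qssa_factors",
    "radical_closed_form",
    "radical_pair_numeric",
    "radical_weak_inhibition",
    "oxygen_supply",
    "simulate_qssa",
]

log = logging.getLogger(__name__)


@dataclass
class QssaFactors:
    """Algebraic quasi-steady factors at one state point (vectorized)."""

    g: np.ndarray        # triplet partition factor, 1/mM
    g_prime: np.ndarray  # singlet-oxygen partition factor, dimensionless
    B: np.ndarray        # radical drive b I C g A, mM/s
    G: np.ndarray        # radical sink sum, 1/s
    T: np.ndarray        # quasi-steady triplet (shorthand b I g C)
    X: np.ndarray        # quasi-steady singlet oxygen


def qssa_factors(C, O2, A, I, params: ParamBundle) -> QssaFactors:
    """Partition factors and radical drive at the given concentrations.

    g uses the triplet--monomer constant in numerator and denominator
    (the constant that quenches T in the full model), so that g*A is the
    fraction of triplets converted to radicals and g -> 1/A when the
    monomer channel dominates.
    """
    C = np.asarray(C, dtype=float)
    O2 = np.asarray(O2, dtype=float)
    A = np.asarray(A, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(C < 0) or np.any(O2 < 0) or np.any(A < 0):
        raise ParameterError("concentrations must be non-negative")
    r = params.rates
    b = params.optics.b_exc
    denom_g = r.k3 * O2 + r.k_tm * A + r.k5
    if np.any(denom_g == 0):
        raise ParameterError("degenerate input: triplet sink terms all vanish")
    g = r.k_tm / denom_g
    kxm_sink = r.k_tm if params.options.g_prime_as_printed else r.k_xm
    denom_gp = r.k6 + r.k11 * C + kxm_sink * A
    with np.errstate(divide="ignore", invalid="ignore"):
        g_prime = np.where(denom_gp > 0, r.k3 / np.maximum(denom_gp, 1e-300), 0.0)
    B = b * I * C * g * A
    T = b * I * g * C
    if params.options.x_qss_as_printed:
        X = np.where(r.k_xm > 0, b * I * C * g_prime * O2 / max(r.k_xm, 1e-300), 0.0)
    else:
        X = T * g_prime * O2
    Rp = np.sqrt(np.maximum(B, 0.0) / r.kT) if r.kT > 0 else np.zeros_like(B)
    G = _sink_sum(params, A, O2, Rp)
    return QssaFactors(g=g, g_prime=g_prime, B=B, G=G, T=T, X=X)


def _sink_sum(params: ParamBundle, A, O2, Rp) -> np.ndarray:
    """G = ki O2 + 2 k12 R' + kp A, restricted to the enabled sink terms."""
    r = params.rates
    sinks = params.options.radical_sinks
    G = np.zeros(np.broadcast(np.asarray(A), np.asarray(O2)).shape)
    if "oxygen" in sinks:
        G = G + r.ki * np.asarray(O2, dtype=float)
    if "cross" in sinks:
        G = G + 2.0 * r.k12 * np.asarray(Rp, dtype=float)
    if "propagation" in sinks:
        G = G + r.kp * np.asarray(A, dtype=float)
    return G


def radical_closed_form(B, G, kT):
    """Non-negative root of 2 kT R^2 + G R - 2 B = 0:

        R = [-G + sqrt(G^2 + 16 kT B)] / (4 kT)

    evaluated in the cancellation-safe form 4B / (G + sqrt(G^2 + 16 kT B)).
    """
    B = np.asarray(B, dtype=float)
    G = np.asarray(G, dtype=float)
    if kT <= 0:
        raise ParameterError("kT must be positive")
    if np.any(B < 0) or np.any(G < 0):
        raise ParameterError("B and G must be non-negative")
    disc = np.sqrt(G * G + 16.0 * kT * B)
    denom = G + disc
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, 4.0 * B / np.maximum(denom, 1e-300), 0.0)
    if R.ndim == 0:
        return float(R)
    return R


def radical_pair_numeric(
    B: float,
    kT: float,
    k12: float,
    kpA: float = 0.0,
    kiO2: float = 0.0,
    tol: float = 1e-14,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Steady-state radical pair (R', R) by damped Newton iteration.

    Solves  2B - k12 R R' - 2 kT R'^2 = 0  and
    2 kT R'^2 - kpA R - k12 R R' - 2 kT R^2 - kiO2 R = 0,
    seeded from the decoupled solution R' = sqrt(B/kT).
    """
    if B < 0:
        raise ParameterError("B must be non-negative")
    if kT <= 0:
        raise ParameterError("kT must be positive")
    if B == 0:
        return 0.0, 0.0
    Rp = math.sqrt(B / kT)
    G0 = kiO2 + 2.0 * k12 * Rp + kpA
    R = float(radical_closed_form(B, G0, kT))

    def residuals(Rp: float, R: float) -> tuple[float, float]:
        f1 = 2.0 * B - k12 * R * Rp - 2.0 * kT * Rp * Rp
        f2 = (2.0 * kT * Rp * Rp - kpA * R - k12 * R * Rp
              - 2.0 * kT * R * R - kiO2 * R)
        return f1, f2

    scale = max(B, kT * Rp * Rp, 1e-300)
    for _ in range(max_iter):
        f1, f2 = residuals(Rp, R)
        if max(abs(f1), abs(f2)) < tol * scale:
            return Rp, R
        # Jacobian
        j11 = -k12 * R - 4.0 * kT * Rp     # df1/dRp
        j12 = -k12 * Rp                    # df1/dR
        j21 = 4.0 * kT * Rp - k12 * R      # df2/dRp
        j22 = -kpA - k12 * Rp - 4.0 * kT * R - kiO2  # df2/dR
        det = j11 * j22 - j12 * j21
        if det == 0:
            break
        dRp = -(f1 * j22 - j12 * f2) / det
        dR = -(j11 * f2 - f1 * j21) / det
        lam = 1.0
        n0 = abs(f1) + abs(f2)
        while lam > 1e-8:
            Rp_new = max(Rp + lam * dRp, 0.0)
            R_new = max(R + lam * dR, 0.0)
            g1, g2 = residuals(Rp_new, R_new)
            if abs(g1) + abs(g2) < n0:
                Rp, R = Rp_new, R_new
                break
            lam *= 0.5
        else:
            break
    f1, f2 = residuals(Rp, R)
    if max(abs(f1), abs(f2)) > 1e-8 * scale:
        raise RuntimeError(
            f"radical pair Newton did not converge: residuals ({f1:.3e}, {f2:.3e})"
        )
    return Rp, R


def radical_weak_inhibition(B: float, O2: float, ki: float, kT: float) -> float:
    """First-order oxygen-inhibited radical in the weak-sink regime:

        R = sqrt(B/kT) - ki O2 (1 - B') / (4 kT),
        B' = 0.5 ki O2 / sqrt(8 B kT).

    Valid for (ki O2)^2 << 8 kT B (warned otherwise); clipped at 0.
    """
    if kT <= 0:
        raise ParameterError("kT must be positive")
    if B < 0 or O2 < 0 or ki < 0:
        raise ParameterError("B, O2, ki must be non-negative")
    if B == 0:
        return 0.0
    G = ki * O2
    if G * G > 0.5 * 8.0 * kT * B:
        warnings.warn(
            "weak-inhibition expansion outside its regime (G^2 not << 8 kT B)",
            stacklevel=2,
        )
    Bp = 0.5 * G / math.sqrt(8.0 * B * kT)
    R = math.sqrt(B / kT) - G * (1.0 - Bp) / (4.0 * kT)
    if R < 0:
        warnings.warn("weak-inhibition radical clipped at 0", stacklevel=2)
        return 0.0
    return R


def oxygen_supply(O2, Y0: float, P_max: float):
    """Saturating replenishment P = (1 - O2/Y0) P_max, floored at 0."""
    if P_max < 0:
        raise ParameterError("P_max must be >= 0")
    if P_max == 0:
        return np.zeros_like(np.asarray(O2, dtype=float)) if np.ndim(O2) else 0.0
    if Y0 <= 0:
        raise ParameterError("P_max > 0 requires Y0 > 0")
    P = (1.0 - np.asarray(O2, dtype=float) / Y0) * P_max
    P = np.maximum(P, 0.0)
    if np.ndim(O2) == 0:
        return float(P)
    return P


def _effective_kp_kT(params: ParamBundle, efficacy: np.ndarray):
    """Per-node (kp, kT) after the conversion-dependent viscosity rescale.

    Only the propagation constant is attenuated: feeding the empirical
    termination attenuation into the radical steady state would *raise*
    kp/sqrt(kT) (gel auto-acceleration) and invert the documented
    viscosity-lowers-efficacy behavior.
    """
    r = params.rates
    if not (params.viscosity.enabled and params.viscosity.v > 0):
        return r.kp, r.kT
    eff = np.clip(efficacy, 0.0, 1.0 - 1e-12)
    f_kp, _f_kT = viscosity_scale(eff, params.viscosity.v)
    return r.kp * f_kp, r.kT


def simulate_qssa(
    params: ParamBundle,
    tier: str = "simplified",
    nz: int = 61,
    nt: int = 121,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the QSSA-reduced kinetics with a live light field.

    The intensity is recomputed from the current photosensitizer field at
    every right-hand-side evaluation (dynamic Beer-Lambert transport).
    Fast-species fields (T, X, R', R) are reconstructed algebraically on
    the output grid.
    """
    if tier not in ("reduced3", "simplified"):
        raise ParameterError(f"unknown tier {tier!r}")
    irr = params.irr
    irr.default_grids(params.init.H, nz=nz, nt=nt)
    z = irr.z_grid
    t_grid = irr.t_grid
    optics = params.optics
    init = params.init
    r = params.rates
    b = optics.b_exc
    n = z.size
    regen = params.options.regeneration
    k_ratio = r.k11 / r.k_xm if r.k_xm > 0 else 0.0

    def unpack(y: np.ndarray):
        C = np.clip(y[:n], 0.0, None)
        O2 = np.clip(y[n:2 * n], 0.0, None)
        A = np.clip(y[2 * n:], 0.0, None)
        return C, O2, A

    def intensity(C: np.ndarray) -> np.ndarray:
        Af = light.absorbance(np.clip(C, 0.0, init.C0), optics, init.C0)
        return light.propagate_intensity(Af, irr.I0, z).I

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        C, O2, A = unpack(y)
        I = intensity(C)
        eff = 1.0 - A / init.A0
        kp_eff, kT_eff = _effective_kp_kT(params, eff)
        fac = qssa_factors(C, O2, A, I, params)
        if np.any(~np.isfinite(fac.B)):
            raise RuntimeError("non-finite radical drive in QSSA RHS")
        kT_arr = kT_eff if np.ndim(kT_eff) else np.full(n, float(kT_eff))
        B_rad = params.options.radical_drive_factor * fac.B
        Rp = np.sqrt(np.maximum(B_rad, 0.0) / kT_arr)
        G = _sink_sum(params, A, O2, Rp)
        # recompute G with per-node kp if viscosity rescaled it
        if np.ndim(kp_eff) and "propagation" in params.options.radical_sinks:
            G = G - r.kp * A + kp_eff * A
        disc = np.sqrt(G * G + 16.0 * kT_arr * B_rad)
        R = np.where(G + disc > 0, 4.0 * B_rad / np.maximum(G + disc, 1e-300), 0.0)
        P = oxygen_supply(O2, init.Y0, init.P_max) if init.P_max > 0 else 0.0
        if tier == "simplified":
            dC = -b * I * C
            dO2 = -r.ki * R * O2 + P
            dA = -kp_eff * R * A
        else:
            RE = (r.ki * R * O2 + 2.0 * kT_arr * R * R) if regen else 0.0
            dC = -b * I * (fac.g * A + k_ratio * fac.g * fac.g_prime * C * O2) * C + RE
            dO2 = -(b * I * C * fac.g + r.ki * R) * O2 + P
            dA = -(b * I * fac.g * C * (1.0 + fac.g_prime * O2) + kp_eff * R) * A
        return np.concatenate([dC, dO2, dA])

    y0 = np.concatenate([
        np.full(n, init.C0),
        np.full(n, init.Y0),
        np.full(n, init.A0),
    ])
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"QSSA solver failed near t = {sol.t[-1] if sol.t.size else 0:.3g} s: "
            f"{sol.message}; consider loosening rtol/atol"
        )
    nt_out = t_grid.size
    C = np.clip(sol.y[:n, :], 0.0, None)
    O2 = np.clip(sol.y[n:2 * n, :], 0.0, None)
    A = np.clip(sol.y[2 * n:, :], 0.0, None)
    I = np.empty_like(C)
    T = np.empty_like(C)
    X = np.empty_like(C)
    Rp_f = np.empty_like(C)
    R_f = np.empty_like(C)
    for j in range(nt_out):
        I[:, j] = intensity(C[:, j])
        fac = qssa_factors(C[:, j], O2[:, j], A[:, j], I[:, j], params)
        eff = 1.0 - A[:, j] / init.A0
        kp_eff, kT_eff = _effective_kp_kT(params, eff)
        kT_arr = kT_eff if np.ndim(kT_eff) else np.full(n, float(kT_eff))
        B_rad = params.options.radical_drive_factor * fac.B
        Rp_f[:, j] = np.sqrt(np.maximum(B_rad, 0.0) / kT_arr)
        G = _sink_sum(params, A[:, j], O2[:, j], Rp_f[:, j])
        disc = np.sqrt(G * G + 16.0 * kT_arr * B_rad)
        R_f[:, j] = np.where(
            G + disc > 0, 4.0 * B_rad / np.maximum(G + disc, 1e-300), 0.0
        )
        T[:, j] = fac.T
        X[:, j] = fac.X
    return Trajectory(
        z_grid=z,
        t_grid=t_grid,
        fields={"C": C, "O2": O2, "A": A, "I": I, "T": T, "X": X,
                "Rp": Rp_f, "R": R_f},
        A0=init.A0,
        diagnostics={
            "tier": tier,
            "n_rhs_evals": int(sol.nfev),
            "rtol": rtol,
            "atol": atol,
        },
        metadata={"model": f"qssa:{tier}"},
    )
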