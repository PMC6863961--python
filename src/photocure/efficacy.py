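"""Closed-form conversion efficacy and induction-time layer.

Under bimolecular termination the converted monomer fraction is
C_EFF = 1 - exp(-S) with S the time integral of kp * R.  With the radical
R = sqrt(0.5 B / kT), the analytic intensity/photosensitizer pair yields

    S(z, t) = K sqrt(0.5 b I0 C0 X) [1 - exp(-B'' t'')] / B''

with K = kp/sqrt(kT), X = exp(-A2 z), B' = b I0 exp(-A'' z),
B'' = 0.5 (B' - 0.5 A1 t) and t'' = t - T_ID.  The same S is available by
direct quadrature of kp * R, which is the authoritative definition: the
closed form is validated against it rather than against its (garbled)
printed rendering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .light import averaged_absorbance, initial_absorbance
from .params import ParamBundle, ParameterError
from .viscosity import effective_K_correction

__all__ = [
    "NO_CURE",
    "SFunctionParams",
    "EfficacyProfile",
    "efficacy_from_S",
    "induction_time",
    "oxygen_linear",
    "oxygen_exponential",
    "s_function",
    "s_infinity",
    "efficacy_profile",
    "fit_scaling_exponent",
]

log = logging.getLogger(__name__)

#: sentinel for "threshold never reached"
NO_CURE = math.inf


@dataclass
class SFunctionParams:
    """Frozen coefficients of the closed-form S at one depth."""

    K: float          # kp / sqrt(kT)
    X_att: float      # depth attenuation exp(-A2 z)
    B_p: float        # surface-referred PS depletion rate B', 1/s
    B_pp: float       # effective decay rate B'' = 0.5 (B' - 0.5 A1 t), 1/s
    t_ind: float = 0.0
    S_T: float | None = None
    C_T: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.X_att <= 1):
            raise ParameterError("X_att must lie in (0, 1]")
        if self.S_T is not None and self.C_T is not None:
            expect = math.log(1.0 / (1.0 - self.C_T))
            if abs(self.S_T - expect) > 1e-12 * max(1.0, abs(expect)):
                raise ParameterError("S_T and C_T inconsistent: S_T != ln(1/(1-C_T))")


@dataclass
class EfficacyProfile:
    """Accumulated exponent, efficacy and regime labels on (z, t) grids."""

    z_grid: np.ndarray
    t_grid: np.ndarray
    S: np.ndarray          # (nz, nt)
    efficacy: np.ndarray   # (nz, nt)
    regime: np.ndarray     # (nz, nt), strings

    def to_frame(self):
        import pandas as pd

        nz, nt = self.S.shape
        return pd.DataFrame({
            "z_cm": np.repeat(self.z_grid, nt),
            "t_s": np.tile(self.t_grid, nz),
            "S": self.S.ravel(),
            "efficacy": self.efficacy.ravel(),
            "regime": self.regime.ravel(),
        })


def efficacy_from_S(S):
    """Conversion efficacy 1 - exp(-S); S must be non-negative."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ParameterError("S must be >= 0")
    out = -np.expm1(-S)
    if out.ndim == 0:
        return float(out)
    return out


def induction_time(k_ratio: float, Y0: float, kp: float, B: float) -> float:
    """T_ID = pi * k * Y0 / (4 kp B), the zero of the linear oxygen decay.

    Returns the no-cure sentinel (inf) when the drive kp * B vanishes
    with oxygen present.
    """
    if Y0 < 0 or k_ratio < 0 or kp < 0 or B < 0:
        raise ParameterError("induction_time arguments must be non-negative")
    if Y0 == 0:
        return 0.0
    if kp * B == 0:
        return NO_CURE
    return math.pi * k_ratio * Y0 / (4.0 * kp * B)


def oxygen_linear(t, Y0: float, kp: float, B: float, k_ratio: float = 1.0):
    """Pre-induction oxygen [O2](t) = max(0, Y0 - 4 kp B t / (pi k))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    O2 = np.maximum(0.0, Y0 - 4.0 * kp * B * t / (math.pi * k_ratio))
    if O2.ndim == 0:
        return float(O2)
    return O2


def oxygen_exponential(t, Y0: float, S_accumulator):
    """[O2](t) = Y0 exp(-S'(t)) for a non-decreasing exponent S'(t).

    ``S_accumulator`` may be a callable of t or an array aligned with t.
    """
    t = np.asarray(t, dtype=float)
    S = S_accumulator(t) if callable(S_accumulator) else np.asarray(S_accumulator)
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ParameterError("S' must be >= 0")
    if S.ndim and np.any(np.diff(S) < -1e-12):
        raise ParameterError("S' must be non-decreasing")
    out = Y0 * np.exp(-S)
    if out.ndim == 0:
        return float(out)
    return out


def _a1(params: ParamBundle, z) -> np.ndarray:
    """Bleaching-rate coefficient of the analytic absorption A' = A2 - A1 t."""
    o = params.optics
    base = 2.3 * (o.a_ps - o.b_prod) * params.init.C0 * params.irr.I0 * o.b_exc
    if params.options.a1_variant == "as_printed":
        return base * np.asarray(z, dtype=float)
    return np.full_like(np.asarray(z, dtype=float), base)


def _closed_form_S1(params: ParamBundle, z, t, t_ind: float, use_a1: bool):
    """Uncorrected (first-order) closed-form S on broadcast (z, t)."""
    o = params.optics
    init = params.init
    irr = params.irr
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    zz, tt = np.broadcast_arrays(z, t)
    A2 = initial_absorbance(o, init.C0)
    A_avg = averaged_absorbance(o, init.C0)
    X_att = np.exp(-A2 * zz)
    B_p = o.b_exc * irr.I0 * np.exp(-A_avg * zz)
    A1 = _a1(params, zz) if use_a1 else np.zeros_like(zz)
    t_dd = np.maximum(0.0, tt - t_ind)
    B_pp = 0.5 * (B_p - 0.5 * A1 * tt)
    D = params.K * np.sqrt(0.5 * o.b_exc * irr.I0 * init.C0 * X_att)
    # growth factor [1 - exp(-B'' t'')]/B'', with the B'' -> 0 limit t''
    small = B_pp * t_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        Gfac = np.where(
            B_pp > 0, -np.expm1(-np.maximum(small, 0.0)) / np.where(B_pp > 0, B_pp, 1.0),
            t_dd,
        )
    if np.any(B_pp <= 0):
        log.debug("B'' <= 0 at %d points; using the linear-growth limit",
                  int(np.sum(B_pp <= 0)))
    return D * Gfac


def _apply_viscosity(params: ParamBundle, S1):
    if params.viscosity.enabled and params.viscosity.m > 0:
        return S1 * effective_K_correction(S1, params.viscosity.m)
    return S1


def s_function(
    z,
    t,
    params: ParamBundle,
    variant: str = "closed_form",
    t_ind: float = 0.0,
    include_oxygen: bool = False,
    use_a1: bool = False,
    apply_viscosity: bool | None = None,
    k_ratio: float = 1.0,
):
    """Accumulated efficacy exponent S(z, t).

    ``variant="closed_form"`` evaluates the frozen-coefficient analytic
    expression; ``"quadrature"`` integrates kp * R numerically with
    R = sqrt(0.5 B / kT) (minus the K12 [O2] correction when
    ``include_oxygen``), using the analytic I and C fields.  ``use_a1``
    switches on the time-dependent absorption correction; the closed
    form then freezes B'' at the evaluation time.
    """
    if variant not in ("closed_form", "quadrature"):
        raise ParameterError(f"unknown s_function variant {variant!r}")
    if apply_viscosity is None:
        apply_viscosity = params.viscosity.enabled
    if variant == "closed_form":
        S1 = _closed_form_S1(params, z, t, t_ind, use_a1)
        S = _apply_viscosity(params, S1) if apply_viscosity else S1
        if np.ndim(S) == 0:
            return float(S)
        return S

    # quadrature path
    o = params.optics
    init = params.init
    irr = params.irr
    r = params.rates
    A2 = initial_absorbance(o, init.C0)
    A_avg = averaged_absorbance(o, init.C0)
    zz = np.atleast_1d(np.asarray(z, dtype=float))
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    zz_b, tt_b = np.broadcast_arrays(zz, tt)
    out = np.empty(zz_b.shape)
    K = params.K

    def integrand_factory(zi: float):
        X_att = math.exp(-A2 * zi)
        B_p = o.b_exc * irr.I0 * math.exp(-A_avg * zi)
        A1 = float(_a1(params, zi)) if use_a1 else 0.0
        B0 = o.b_exc * irr.I0 * init.C0

        def R_of_t(tp: float) -> float:
            A_prime = A2 - A1 * tp
            I = irr.I0 * math.exp(-A_prime * zi)
            C = init.C0 * math.exp(-B_p * tp)
            B = o.b_exc * I * C
            Rfree = math.sqrt(0.5 * B / r.kT)
            if include_oxygen and init.Y0 > 0:
                T_id = induction_time(k_ratio, init.Y0, r.kp, B0 * X_att)
                O2 = oxygen_linear(tp, init.Y0, r.kp, B0 * X_att, k_ratio) \
                    if math.isfinite(T_id) else init.Y0
                Bp_weak = 0.5 * r.ki * O2 / math.sqrt(8.0 * max(B, 1e-300) * r.kT)
                # oxygen correction carries the inhibition constant; the
                # weak-inhibition factor is clipped inside [0, 1]
                K12 = r.ki * (1.0 - min(Bp_weak, 1.0)) / (4.0 * r.kT)
                return max(0.0, Rfree - K12 * O2)
            return Rfree

        return R_of_t

    cache: dict[float, object] = {}
    flat_z = zz_b.ravel()
    flat_t = tt_b.ravel()
    flat_out = out.ravel()
    for i in range(flat_out.size):
        zi, ti = float(flat_z[i]), float(flat_t[i])
        fn = cache.get(zi)
        if fn is None:
            fn = integrand_factory(zi)
            cache[zi] = fn
        if include_oxygen:
            lo, hi = 0.0, ti
        else:
            # oxygen ignored: the clock starts at t_ind (shifted time t'')
            lo, hi = 0.0, max(0.0, ti - t_ind)
        if hi <= lo:
            flat_out[i] = 0.0
            continue
        val, _err = quad(fn, lo, hi, limit=200, epsabs=1e-13, epsrel=1e-11)
        flat_out[i] = r.kp * val
    S = out
    if apply_viscosity:
        S = _apply_viscosity(params, S)
    if np.ndim(z) == 0 and np.ndim(t) == 0:
        return float(S.ravel()[0])
    return S.reshape(np.broadcast(np.asarray(z), np.asarray(t)).shape)


def s_infinity(params: ParamBundle, z=0.0):
    """Steady-state exponent S(t -> inf) of the closed form with A1 = 0:

        S_inf = K sqrt(0.5 b I0 C0 X) / (0.5 B')

    which carries the (C0/I0)^0.5 steady-state scaling.
    """
    o = params.optics
    init = params.init
    irr = params.irr
    z = np.asarray(z, dtype=float)
    A2 = initial_absorbance(o, init.C0)
    A_avg = averaged_absorbance(o, init.C0)
    X_att = np.exp(-A2 * z)
    B_p = o.b_exc * irr.I0 * np.exp(-A_avg * z)
    if irr.I0 == 0 or o.b_exc == 0:
        return np.zeros_like(z) if z.ndim else 0.0
    out = params.K * np.sqrt(0.5 * o.b_exc * irr.I0 * init.C0 * X_att) / (0.5 * B_p)
    if out.ndim == 0:
        return float(out)
    return out


def efficacy_profile(
    params: ParamBundle,
    z_grid: np.ndarray,
    t_grid: np.ndarray,
    t_ind: float = 0.0,
    use_a1: bool = False,
    steady_fraction: float = 0.95,
) -> EfficacyProfile:
    """Closed-form S/efficacy fields with induction/rising/steady labels."""
    z = np.asarray(z_grid, dtype=float)[:, None]
    t = np.asarray(t_grid, dtype=float)[None, :]
    S = np.asarray(s_function(z, t, params, "closed_form", t_ind=t_ind, use_a1=use_a1))
    eff = efficacy_from_S(S)
    S_inf = np.asarray(s_infinity(params, z))
    regime = np.full(S.shape, "rising", dtype=object)
    regime[np.broadcast_to(t, S.shape) <= t_ind] = "induction"
    with np.errstate(invalid="ignore", divide="ignore"):
        steady = S >= steady_fraction * np.where(S_inf > 0, S_inf, np.inf)
    regime[steady] = "steady"
    return EfficacyProfile(
        z_grid=np.asarray(z_grid, dtype=float),
        t_grid=np.asarray(t_grid, dtype=float),
        S=S,
        efficacy=np.asarray(eff),
        regime=regime,
    )


def fit_scaling_exponent(quantity_samples, driver_samples) -> float:
    """Least-squares slope of log(quantity) against log(driver).

    Diagnoses power-law scaling claims (for example S_inf vs I0 -> -1/2).
    Samples must be positive; fewer than 4 samples or a span under one
    decade triggers a warning, not an error.
    """
    y = np.asarray(quantity_samples, dtype=float)
    x = np.asarray(driver_samples, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ParameterError("samples must be 1-D arrays of equal length")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ParameterError("scaling fit requires positive samples")
    if y.size < 4 or (x.max() / x.min()) < 10.0:
        warnings.warn(
            "scaling fit with < 4 samples or < 1 decade of driver span",
            stacklevel=2,
        )
    slope, _intercept = np.polyfit(np.log(x), np.log(y), 1)
    return float(slope)
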