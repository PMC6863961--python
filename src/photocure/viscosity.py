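"""Conversion-dependent rate constants (gel / free-volume effect).

As conversion raises viscosity, both the propagation constant kp and the
bimolecular termination constant kT fall.  The empirical forms used here
(CGS units, cm^3/(mM s)) are

    E' = exp(v * C_EFF)
    kp(C_EFF) = 1865 / (1 + 2e-9 * E')
    kT(C_EFF) = 1e7 / (2.3 + E') + kp(C_EFF) * (1 - C_EFF)

with v in roughly 25-40.  The numeric tiers rescale their preset (kp, kT)
by the *ratio* of these forms to their zero-conversion values, since
preset constants are not stated on an absolute scale.  The analytic layer
instead shrinks the effective constant K = kp/sqrt(kT) by the multiplier
1 - m (1 - exp(-S)).
"""

from __future__ import annotations

import math

import numpy as np

from .params import ParameterError

__all__ = [
    "rates_vs_conversion",
    "viscosity_scale",
    "effective_K_correction",
]

_KP0 = 1865.0
_KP_DENOM_COEF = 2e-9
_KT_NUM = 1e7
_KT_DENOM_OFFSET = 2.3


def rates_vs_conversion(C_EFF, v: float):
    """(kp_eff, kT_eff) at conversion ``C_EFF`` for viscosity strength ``v``.

    Accepts scalars or arrays; C_EFF must lie in [0, 1).
    """
    c = np.asarray(C_EFF, dtype=float)
    if np.any((c < 0) | (c >= 1)):
        raise ParameterError("C_EFF must lie in [0, 1)")
    if v < 0:
        raise ParameterError("v must be >= 0")
    E = np.exp(v * c)
    kp = _KP0 / (1.0 + _KP_DENOM_COEF * E)
    kT = _KT_NUM / (_KT_DENOM_OFFSET + E) + kp * (1.0 - c)
    if np.isscalar(C_EFF) or np.ndim(C_EFF) == 0:
        return float(kp), float(kT)
    return kp, kT


def viscosity_scale(C_EFF, v: float):
    """Dimensionless attenuation factors (f_kp, f_kT) relative to C_EFF = 0.

    Multiplying a preset (kp, kT) by these reproduces the conversion
    dependence without committing to the absolute magnitudes above.
    """
    kp0, kT0 = rates_vs_conversion(0.0, v)
    kp, kT = rates_vs_conversion(C_EFF, v)
    return kp / kp0, kT / kT0


def effective_K_correction(S_first_order, m: float):
    """Multiplier 1 - m (1 - exp(-S)) applied to K in the analytic layer.

    ``S_first_order`` is the uncorrected exponent; m in [0, 1).
    """
    if not (0 <= m < 1):
        raise ParameterError("m must lie in [0, 1)")
    S = np.asarray(S_first_order, dtype=float)
    if np.any(S < 0):
        raise ParameterError("S must be >= 0")
    out = 1.0 - m * (1.0 - np.exp(-S))
    if np.ndim(S_first_order) == 0:
        return float(out)
    return out
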