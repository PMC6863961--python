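"""Full seven-species kinetics by method of lines.

Per depth node the state is (C, T, R', R, X, O2, A): ground and triplet
photosensitizer, the two carbon radicals, singlet oxygen, ground-state
oxygen and monomer.  The light field is recomputed from the current
photosensitizer profile at every right-hand-side evaluation, so the
dynamic (non-Beer-Lambert) attenuation is exact to solver tolerance.

The stiff fast species (T, R', R, X) make this tier expensive; it exists
as the reference the QSSA reductions are validated against.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import light
from .params import ParamBundle, ParameterError
from .qssa import oxygen_supply
from .trajectory import Trajectory
from .viscosity import viscosity_scale

__all__ = ["full_rhs", "simulate_full", "mass_balance_report", "scale_for_stiff_limit"]

SPECIES = ("C", "T", "Rp", "R", "X", "O2", "A")


def full_rhs(
    state: dict[str, np.ndarray], I_at_nodes: np.ndarray, params: ParamBundle
) -> dict[str, np.ndarray]:
    """Time derivatives of every species at every depth node.

    ``state`` maps species name to a per-node array; ``I_at_nodes`` is the
    intensity evaluated at the same nodes.  The optional regeneration
    term R_E = ki R O2 + 2 kT (R^2 + R'^2) returns terminated radicals
    and quenched oxygen to the photosensitizer ground state.
    """
    r = params.rates
    b = params.optics.b_exc
    C, T, Rp, R, X, O2, A = (np.asarray(state[s], dtype=float) for s in SPECIES)
    I = np.asarray(I_at_nodes, dtype=float)
    if params.viscosity.enabled and params.viscosity.v > 0:
        # propagation only; see qssa._effective_kp_kT for why kT stays
        eff = np.clip(1.0 - A / params.init.A0, 0.0, 1.0 - 1e-12)
        f_kp, _ = viscosity_scale(eff, params.viscosity.v)
        kp, kT = r.kp * f_kp, r.kT
    else:
        kp, kT = r.kp, r.kT

    P = oxygen_supply(O2, params.init.Y0, params.init.P_max) \
        if params.init.P_max > 0 else 0.0
    RE = r.ki * R * O2 + 2.0 * kT * (R * R + Rp * Rp) \
        if params.options.regeneration else 0.0

    # optional radical sinks mirror the QSSA G-term switches so that every
    # tier shares one radical budget; oxygen scavenging always stays (it
    # is paired with the O2 balance)
    sinks = params.options.radical_sinks
    prop_sink = kp * R * A if "propagation" in sinks else 0.0
    cross_sink = r.k12 * R * Rp if "cross" in sinks else 0.0

    d = {
        "C": -b * I * C - r.k11 * X * C + (r.k5 + r.k3 * O2) * T + RE,
        "T": b * I * C - (r.k5 + r.k3 * O2 + r.k_tm * A) * T,
        "Rp": 2.0 * r.k_tm * T * A - cross_sink - 2.0 * kT * Rp * Rp,
        "R": (2.0 * kT * Rp * Rp - prop_sink - cross_sink
              - 2.0 * kT * R * R - r.ki * R * O2),
        "X": r.k3 * O2 * T - (r.k6 + r.k11 * C + r.k_xm * A) * X,
        "O2": P - r.k3 * O2 * T + r.k6 * X - r.ki * R * O2,
        "A": -(r.k_tm * T + r.k_xm * X + kp * R) * A,
    }
    for name, arr in d.items():
        bad = ~np.isfinite(arr)
        if np.any(bad):
            node = int(np.nonzero(np.atleast_1d(bad))[0][0])
            raise RuntimeError(
                f"non-finite derivative in d{name}/dt at node {node}"
            )
    return d


def simulate_full(
    params: ParamBundle,
    nz: int = 61,
    nt: int = 121,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full system; returns a Trajectory with all species.

    An auxiliary state accumulates the monomer sink integral
    int (k_tm T + k_xm X + kp R) A dt so that the material balance of the
    monomer channel can be checked to solver accuracy afterwards.
    """
    irr = params.irr
    irr.default_grids(params.init.H, nz=nz, nt=nt)
    z = irr.z_grid
    t_grid = irr.t_grid
    init = params.init
    optics = params.optics
    r = params.rates
    n = z.size
    ns = len(SPECIES)

    def intensity(C: np.ndarray) -> np.ndarray:
        Af = light.absorbance(np.clip(C, 0.0, init.C0), optics, init.C0)
        return light.propagate_intensity(Af, irr.I0, z).I

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        state = {s: np.clip(y[i * n:(i + 1) * n], 0.0, None)
                 for i, s in enumerate(SPECIES)}
        I = intensity(state["C"])
        d = full_rhs(state, I, params)
        if params.viscosity.enabled and params.viscosity.v > 0:
            eff = np.clip(1.0 - state["A"] / init.A0, 0.0, 1.0 - 1e-12)
            f_kp, _ = viscosity_scale(eff, params.viscosity.v)
            kp = r.kp * f_kp
        else:
            kp = r.kp
        sink = (r.k_tm * state["T"] + r.k_xm * state["X"]
                + kp * state["R"]) * state["A"]
        return np.concatenate([d[s] for s in SPECIES] + [sink])

    y0 = np.zeros((ns + 1) * n)
    y0[:n] = init.C0                       # C
    y0[5 * n:6 * n] = init.Y0              # O2
    y0[6 * n:7 * n] = init.A0              # A
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
            f"full-model solver failed near t = {sol.t[-1] if sol.t.size else 0:.3g} s:"
            f" {sol.message}; consider loosening rtol/atol or reducing stiff rates"
        )
    raw = {s: sol.y[i * n:(i + 1) * n, :] for i, s in enumerate(SPECIES)}
    min_excursion = min(float(arr.min()) for arr in raw.values())
    fields = {s: np.clip(arr, 0.0, None) for s, arr in raw.items()}
    I = np.empty_like(fields["C"])
    for j in range(t_grid.size):
        I[:, j] = intensity(fields["C"][:, j])
    fields["I"] = I
    fields["A_sink_integral"] = sol.y[ns * n:, :]
    return Trajectory(
        z_grid=z,
        t_grid=t_grid,
        fields=fields,
        A0=init.A0,
        diagnostics={
            "n_rhs_evals": int(sol.nfev),
            "n_jac_evals": int(sol.njev),
            "n_lu": int(sol.nlu),
            "min_excursion": min_excursion,
            "rtol": rtol,
            "atol": atol,
        },
        metadata={"model": "full"},
    )


def mass_balance_report(traj: Trajectory) -> dict[str, float]:
    """Conservation diagnostics for a full-model trajectory.

    * ``max_negativity``: most negative raw solver excursion (mM);
    * ``monomer_residual_rel``: max |A0 - A - int sink dt| / A0, using the
      co-integrated sink accumulator (solver-accurate, no finite
      differencing).
    """
    if "A_sink_integral" not in traj.fields:
        raise ParameterError("trajectory lacks the co-integrated sink accumulator")
    A = traj.fields["A"]
    S = traj.fields["A_sink_integral"]
    resid = np.abs(traj.A0 - A - S)
    return {
        "max_negativity": max(0.0, -float(traj.diagnostics.get("min_excursion", 0.0))),
        "monomer_residual_rel": float(resid.max() / traj.A0),
    }


def scale_for_stiff_limit(params: ParamBundle, lam: float) -> ParamBundle:
    """Speed up the fast species by ``lam`` while fixing the slow dynamics.

    Linear fast rates (k5, k3, k6, k_tm, k_xm) scale by lam; the radical
    pair rates (kT, k12) by lam^2 and (kp, ki) by lam, so that the
    quasi-steady lumped quantities B, K = kp/sqrt(kT), kp*R and ki*R are
    lam-invariant.  In the lam -> infinity limit the full model converges
    to its QSSA reduction evaluated at the *unscaled* constants.
    """
    scaled = params.rates.scaled(
        k5=lam, k3=lam, k6=lam, k_tm=lam, k_xm=lam, k11=lam,
        kT=lam * lam, k12=lam * lam, kp=lam, ki=lam,
    )
    return params.replace(rates=scaled)
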