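import numpy as np
import pytest

from photocure.params import (
    Irradiation,
    ModelOptions,
    OpticalParams,
    ParamBundle,
    RateConstants,
    StateInit,
    ViscosityParams,
    validate_params,
)


def make_bundle(
    b_exc=0.02,
    a_ps=458.0,
    b_prod=0.0,
    Q=0.0,
    C0=0.01,
    Y0=0.001,
    A0=1.0,
    H=0.03,
    P_max=0.0,
    I0=5.0,
    t_end=300.0,
    rates=None,
    options=None,
    viscosity=None,
) -> ParamBundle:
    """Hand-rolled bundle for tests; defaults mirror the main preset family."""
    return validate_params(
        OpticalParams(a_ps=a_ps, b_prod=b_prod, Q=Q, b_exc=b_exc),
        rates or RateConstants(),
        StateInit(C0=C0, Y0=Y0, A0=A0, H=H, P_max=P_max),
        Irradiation(I0=I0, t_end=t_end),
        viscosity=viscosity,
        options=options,
    )


@pytest.fixture
def fig4_bundle():
    from photocure.params import load_preset

    return load_preset("fig4_panelA").bundle


@pytest.fixture
def oxygen_free_surface_bundle():
    """Single-depth-node, oxygen-free configuration with an exact
    closed-form efficacy (sink-free radical, g*A = 1)."""
    rates = RateConstants(k3=0.0, k5=0.0, k12=0.0, kT=3.4e4, kp=1865.0, ki=0.0)
    b = make_bundle(
        Y0=0.0, I0=10.0, t_end=120.0, rates=rates,
        options=ModelOptions(radical_sinks=()),
    )
    b.irr.z_grid = np.array([0.0])
    return b


@pytest.fixture
def cross_tier_bundle():
    """Slow-bleaching, oxygen-free, optically thick configuration where the
    numeric simplified tier and the analytic curing layer share the same
    radical law (drive factor 0.5, no sinks)."""
    rates = RateConstants(k5=1.0, k12=0.0, kT=3.4e4, kp=1865.0, ki=0.0)
    return make_bundle(
        b_exc=5e-4, C0=0.1, Y0=0.0, I0=2.0, t_end=400.0, rates=rates,
        options=ModelOptions(radical_sinks=(), radical_drive_factor=0.5),
    )
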