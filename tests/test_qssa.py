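import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photocure as pc
from photocure.params import ModelOptions, ParameterError, RateConstants
from photocure.qssa import (
    oxygen_supply,
    qssa_factors,
    radical_closed_form,
    radical_pair_numeric,
    radical_weak_inhibition,
    simulate_qssa,
)
from tests.conftest import make_bundle


class TestQssaFactors:
    def test_monomer_dominant_limit(self, fig4_bundle):
        # k_tm A >> k3 O2 + k5 drives g toward 1/A
        b = fig4_bundle
        b.rates.k_tm = 1e8
        f = qssa_factors(0.01, 0.001, 2.0, 5.0, b)
        assert float(f.g) == pytest.approx(0.5, rel=1e-3)

    def test_anoxic_limit(self, fig4_bundle):
        r = fig4_bundle.rates
        f = qssa_factors(0.01, 0.0, 1.0, 5.0, fig4_bundle)
        assert float(f.g) == pytest.approx(r.k_tm / (r.k_tm * 1.0 + r.k5), rel=1e-12)
        # no singlet-oxygen production without oxygen
        assert float(f.X) == 0.0

    def test_partition_bound_saturated(self):
        rates = RateConstants(k3=0.0, k5=0.0)
        b = make_bundle(rates=rates)
        f = qssa_factors(0.01, 0.0, 1.0, 5.0, b)
        assert float(f.g) * 1.0 == pytest.approx(1.0, rel=1e-15)

    def test_partition_bound_general(self, fig4_bundle):
        f = qssa_factors(0.01, 0.001, 1.0, 5.0, fig4_bundle)
        assert float(f.g) * 1.0 <= 1 + 1e-9
        assert float(f.B) >= 0 and float(f.G) >= 0

    def test_degenerate_input(self):
        rates = RateConstants(k3=0.0, k5=0.0)
        b = make_bundle(rates=rates)
        with pytest.raises(ParameterError, match="degenerate"):
            qssa_factors(0.01, 0.0, 0.0, 5.0, b)

    def test_negative_concentration_rejected(self, fig4_bundle):
        with pytest.raises(ParameterError):
            qssa_factors(-0.01, 0.001, 1.0, 5.0, fig4_bundle)


class TestRadicalClosedForm:
    def test_sink_free_limit(self):
        assert radical_closed_form(1e-3, 0.0, 3.4e4) == pytest.approx(
            math.sqrt(1e-3 / 3.4e4), rel=1e-12
        )

    def test_no_drive(self):
        assert radical_closed_form(0.0, 5.0, 3.4e4) == 0.0

    @given(
        logB=st.floats(-10, 0),
        logG=st.floats(-6, 4),
        logkT=st.floats(0, 8),
    )
    @settings(max_examples=300, deadline=None)
    def test_quadratic_residual(self, logB, logG, logkT):
        B, G, kT = 10.0**logB, 10.0**logG, 10.0**logkT
        R = radical_closed_form(B, G, kT)
        resid = 2 * kT * R * R + G * R - 2 * B
        assert abs(resid) < 1e-12 * (2 * B + G * R + 1.0)

    def test_kT_guard(self):
        with pytest.raises(ParameterError):
            radical_closed_form(1.0, 1.0, 0.0)


class TestRadicalPairNumeric:
    def test_decoupled_case(self):
        B, kT, kpA, kiO2 = 1e-3, 3.4e4, 50.0, 0.1
        Rp, R = radical_pair_numeric(B, kT, k12=0.0, kpA=kpA, kiO2=kiO2)
        assert Rp == pytest.approx(math.sqrt(B / kT), rel=1e-10)
        # R solves its scalar quadratic with G = kpA + kiO2
        R_ref = radical_closed_form(B, kpA + kiO2, kT)
        assert R == pytest.approx(R_ref, rel=1e-10)

    def test_zero_drive(self):
        assert radical_pair_numeric(0.0, 3.4e4, 1e4) == (0.0, 0.0)

    def test_residual_oracle_random_box(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            B = 10 ** rng.uniform(-8, -2)
            kT = 10 ** rng.uniform(2, 6)
            k12 = 10 ** rng.uniform(0, 5)
            kpA = 10 ** rng.uniform(-2, 2)
            kiO2 = 10 ** rng.uniform(-4, 0)
            Rp, R = radical_pair_numeric(B, kT, k12, kpA, kiO2)
            f1 = 2 * B - k12 * R * Rp - 2 * kT * Rp**2
            f2 = (2 * kT * Rp**2 - kpA * R - k12 * R * Rp
                  - 2 * kT * R**2 - kiO2 * R)
            scale = max(B, kT * Rp**2)
            assert max(abs(f1), abs(f2)) < 1e-10 * scale

    def test_agrees_with_closed_form_in_weak_coupling(self):
        # k12 R' <= 0.1 (kp A + ki O2): closed form within 2 %
        rng = np.random.default_rng(7)
        for _ in range(100):
            B = 10 ** rng.uniform(-8, -2)
            kT = 10 ** rng.uniform(2, 6)
            kpA = 10 ** rng.uniform(-2, 2)
            kiO2 = 10 ** rng.uniform(-4, 0)
            Rp0 = math.sqrt(B / kT)
            k12 = 0.1 * (kpA + kiO2) / Rp0 * rng.uniform(0, 1)
            _Rp, R = radical_pair_numeric(B, kT, k12, kpA, kiO2)
            G = kiO2 + 2 * k12 * Rp0 + kpA
            assert R == pytest.approx(radical_closed_form(B, G, kT), rel=0.02)


class TestRadicalWeakInhibition:
    def test_oxygen_free_consistency(self):
        B, kT = 1e-3, 3.4e4
        assert radical_weak_inhibition(B, 0.0, 1e3, kT) == pytest.approx(
            radical_closed_form(B, 0.0, kT), rel=1e-12
        )

    def test_taylor_expansion_error(self):
        # |R_weak - R_closed| = O((ki O2)^2 / (kT sqrt(B/kT)))
        B, kT, ki = 1e-3, 3.4e4, 1e3
        R0 = math.sqrt(B / kT)
        errs = []
        for O2 in (1e-5, 2e-5, 4e-5):
            Rw = radical_weak_inhibition(B, O2, ki, kT)
            Rc = radical_closed_form(B, ki * O2, kT)
            errs.append(abs(Rw - Rc))
        # quadratic scaling: doubling O2 quadruples the error (within 30 %)
        assert errs[1] / errs[0] == pytest.approx(4.0, rel=0.3)
        assert errs[2] / errs[1] == pytest.approx(4.0, rel=0.3)
        assert errs[-1] < 0.01 * R0

    def test_decreasing_in_oxygen(self):
        B, kT, ki = 1e-3, 3.4e4, 1e3
        vals = [radical_weak_inhibition(B, O2, ki, kT)
                for O2 in (0.0, 1e-5, 5e-5, 1e-4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_regime_warns(self):
        # G^2 >> 8 kT B: the expansion is meaningless and must say so
        with pytest.warns(UserWarning):
            radical_weak_inhibition(1e-9, 1.0, 1e6, 1e3)


class TestOxygenSupply:
    def test_saturated(self):
        assert oxygen_supply(0.001, 0.001, 1e-3) == 0.0

    def test_maximal(self):
        assert oxygen_supply(0.0, 0.001, 1e-3) == 1e-3

    def test_linear(self):
        assert oxygen_supply(0.0005, 0.001, 1e-3) == pytest.approx(5e-4, rel=1e-12)

    def test_floored_above_Y0(self):
        assert oxygen_supply(0.002, 0.001, 1e-3) == 0.0

    def test_config_error(self):
        with pytest.raises(ParameterError):
            oxygen_supply(0.0, 0.0, 1e-3)


class TestSimulateQssa:
    def test_unknown_tier(self, fig4_bundle):
        with pytest.raises(ParameterError):
            simulate_qssa(fig4_bundle, tier="bogus")

    def test_surface_closed_form_oracle(self, oxygen_free_surface_bundle):
        # dA/dt = -kp sqrt(b I0 C0 e^{-b I0 t} / kT) A at z = 0 integrates to
        # S(t) = K sqrt(b I0 C0) 2 [1 - e^{-b I0 t / 2}] / (b I0)
        b = oxygen_free_surface_bundle
        traj = simulate_qssa(b, tier="simplified", nt=41, rtol=1e-11, atol=1e-14)
        K = b.rates.K
        bI0 = b.optics.b_exc * b.irr.I0
        t = traj.t_grid
        S = K * math.sqrt(bI0 * b.init.C0) * 2.0 * (1 - np.exp(-bI0 * t / 2)) / bI0
        eff_expected = 1.0 - np.exp(-S)
        assert np.max(np.abs(traj.efficacy[0, :] - eff_expected)) < 1e-6

    def test_higher_intensity_shorter_induction(self, fig4_bundle):
        from photocure.params import apply_sweep

        t_inds, finals = [], []
        for I0 in (0.5, 2.0, 5.0, 10.0):
            b = apply_sweep(fig4_bundle, {"I0": I0, "t_end": 60.0})
            traj = simulate_qssa(b, tier="simplified", nz=5, nt=601)
            t_inds.append(traj.induction_times(b.init.Y0)[0])
            finals.append(traj.efficacy[0, -1])
        assert all(a > b for a, b in zip(t_inds, t_inds[1:]))
        assert np.isfinite(t_inds).all()

    def test_induction_increases_with_oxygen(self, fig4_bundle):
        from photocure.params import apply_sweep

        t_inds = []
        for Y0 in (0.0005, 0.001, 0.002):
            b = apply_sweep(fig4_bundle, {"Y0": Y0, "t_end": 60.0})
            traj = simulate_qssa(b, tier="simplified", nz=5, nt=601)
            t_inds.append(traj.induction_times(Y0)[0])
        assert all(a < b for a, b in zip(t_inds, t_inds[1:]))

    def test_supply_lowers_final_efficacy(self, fig4_bundle):
        from photocure.params import apply_sweep

        finals = []
        for P in (0.0, 1e-4, 1e-3, 6e-3):
            b = apply_sweep(fig4_bundle, {"P_max": P})
            traj = simulate_qssa(b, tier="simplified", nz=5, nt=41)
            finals.append(traj.efficacy[0, -1])
        assert all(a > b for a, b in zip(finals, finals[1:]))

    def test_tier_consistency(self):
        # type-II channels off, regeneration off, triplet-monomer dominant:
        # the three-ODE reduction and the simplified system agree to < 1 %
        rates = RateConstants(k3=0.0, k5=1.0, k_xm=0.0, k11=0.0, k12=100.0,
                              kT=3.4e4, kp=1865.0, ki=2e5)
        b = make_bundle(rates=rates,
                        options=ModelOptions(radical_sinks=("oxygen", "cross")))
        t1 = simulate_qssa(b, tier="simplified", nz=7, nt=41)
        t2 = simulate_qssa(b, tier="reduced3", nz=7, nt=41)
        assert np.max(np.abs(t1.efficacy - t2.efficacy)) < 0.01

    def test_no_photochemistry(self):
        b = make_bundle(b_exc=0.0)
        traj = simulate_qssa(b, tier="simplified", nz=5, nt=11)
        np.testing.assert_allclose(traj.fields["C"], b.init.C0, rtol=1e-9)
        np.testing.assert_allclose(traj.fields["A"], b.init.A0, rtol=1e-9)

    def test_trajectory_invariants(self, fig4_bundle):
        traj = simulate_qssa(fig4_bundle, tier="simplified", nz=5, nt=41)
        eff = traj.efficacy
        assert np.all((0 <= eff) & (eff <= 1))
        assert np.all(np.diff(eff, axis=1) >= -1e-10)
        # light attenuates with depth, so shallower nodes convert at least
        # as much -- before saturation (the inverse-sqrt steady-state law
        # lets deep nodes catch up at long times)
        rising = eff[0, :] < 0.8
        assert np.all(eff[:-1, rising] >= eff[1:, rising] - 1e-9)

    def test_csv_round_shape(self, fig4_bundle, tmp_path):
        traj = simulate_qssa(fig4_bundle, tier="simplified", nz=4, nt=9)
        path = tmp_path / "traj.csv"
        traj.to_csv(str(path))
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == 4 * 9
        assert {"z_cm", "t_s", "C", "O2", "A", "I", "efficacy"} <= set(df.columns)
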