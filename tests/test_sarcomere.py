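"""Crossbridge kinetics, myofiber stresses and the force-pCa experiment."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioscale.sarcomere import (CA_GATE_REF, HILL_EXPONENT, CalciumSchedule,
                                   CrossbridgeParams, MyofiberParams, SarcomereError,
                                   WallMechState, active_stress, calcium_gate,
                                   calcium_transient, crossbridge_derivatives,
                                   effective_rates, myofiber_force_balance,
                                   parameter_direction_screen, passive_stress,
                                   pca_curve_summary, simulate_force_pca,
                                   steady_state_fractions, thick_filament_overlap,
                                   viscous_stress, ForcePCaCurve)


class TestCalciumTransient:
    def test_diastolic_floor_at_cycle_start(self):
        cs = CalciumSchedule(Ca_diastole=0.1610, Ca_amplitude=2.0)
        assert calcium_transient(0.0, cs) == pytest.approx(0.1610, abs=1e-12)

    def test_peak_at_end_of_rise(self):
        cs = CalciumSchedule(Ca_diastole=0.1610, Ca_amplitude=2.0)
        assert calcium_transient(cs.T_S, cs) == pytest.approx(2.1610, abs=1e-12)

    def test_half_rise_value(self):
        cs = CalciumSchedule(Ca_diastole=0.1610, Ca_amplitude=2.0)
        expect = 0.1610 + 2.0 * 0.5 * (1 - math.cos(math.pi / 2))
        assert calcium_transient(cs.T_S / 2, cs) == pytest.approx(expect, rel=1e-12)

    def test_continuous_at_segment_boundaries(self):
        cs = CalciumSchedule()
        for t0 in (cs.T_S, cs.T_S + cs.T_R):
            lo = calcium_transient(t0 - 1e-9, cs)
            hi = calcium_transient(t0 + 1e-9, cs)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_floor_is_global_minimum(self):
        cs = CalciumSchedule()
        t = np.linspace(0, cs.T, 500)
        assert np.all(calcium_transient(t, cs) >= cs.Ca_diastole - 1e-12)

    def test_invalid_time_and_schedule_rejected(self):
        cs = CalciumSchedule()
        with pytest.raises(SarcomereError):
            calcium_transient(-0.01, cs)
        with pytest.raises(SarcomereError):
            calcium_transient(cs.T + 0.01, cs)
        with pytest.raises(SarcomereError):
            CalciumSchedule(k_TS=0.6, k_TR=0.6)


class TestEffectiveRates:
    def test_zero_pi_kills_rebinding(self):
        cb = replace(CrossbridgeParams(), Pi=0.0)
        er = effective_rates(cb)
        assert er.km1_eff == 0.0
        assert er.k1_eff == pytest.approx(cb.k_1)

    def test_identity_at_reference_metabolites(self):
        cb = CrossbridgeParams()
        er1, er2 = effective_rates(cb), effective_rates(cb)
        assert er1 == er2
        assert er1.km1_eff == pytest.approx(cb.k_m1 * cb.Pi / 1000.0)

    def test_hyperoxia_metabolite_shift_directions(self):
        """Oracle: direct evaluation of each published rate expression."""
        cb = CrossbridgeParams()
        hx = replace(cb, ATP=cb.ATP * 0.95, ADP=cb.ADP * 1.05, Pi=cb.Pi * 1.05)
        er0, er1 = effective_rates(cb), effective_rates(hx)
        # less ATP + more ADP slows ATP-gated detachment
        phi0 = (cb.ATP / cb.K_T) / (1 + cb.ATP / cb.K_T + cb.ADP / cb.K_D)
        phi1 = (hx.ATP / hx.K_T) / (1 + hx.ATP / hx.K_T + hx.ADP / hx.K_D)
        assert phi1 < phi0
        assert er1.k3_eff < er0.k3_eff
        # more Pi raises the rebinding flux and trims the forward rate
        assert er1.km1_eff > er0.km1_eff
        assert er1.k1_eff < er0.k1_eff

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(SarcomereError):
            replace(CrossbridgeParams(), ATP=-1.0)


class TestCrossbridgeDerivatives:
    def test_absorbing_detached_state(self):
        w = WallMechState()  # fully detached, N_np = 1
        d = crossbridge_derivatives(w, Ca=0.0, overlap=1.0,
                                    rates=effective_rates(CrossbridgeParams()))
        assert np.allclose(d[:9], 0.0)
        assert d[9] == 0.0  # no Ca to bind

    def test_detachment_only_dynamics(self):
        cb = replace(CrossbridgeParams(), k_a=0.0)
        w = WallMechState(p1_0=0.3, p2_0=0.3, p3_0=0.3, N_np=0.0, U_SR=0.05)
        d = crossbridge_derivatives(w, Ca=2.0, overlap=1.0, rates=effective_rates(cb))
        # total attached occupancy strictly decreases until detached
        assert d[0] + d[3] + d[6] < 0.0

    def test_conservation_is_exact(self, rng):
        cb = CrossbridgeParams()
        rates = effective_rates(cb)
        for _ in range(25):
            occ = rng.dirichlet(np.ones(5)) * 0.98
            w = WallMechState(p1_0=occ[0], p2_0=occ[1], p3_0=occ[2], U_SR=occ[3],
                              p1_1=rng.normal(0, 1e-3), p2_1=rng.normal(0, 1e-3),
                              p3_1=rng.normal(0, 1e-3), p1_2=abs(rng.normal(0, 1e-4)),
                              p2_2=abs(rng.normal(0, 1e-4)), p3_2=abs(rng.normal(0, 1e-4)),
                              N_np=rng.uniform(0, 1))
            d = crossbridge_derivatives(w, Ca=rng.uniform(0.1, 3), overlap=rng.uniform(0, 1),
                                        rates=rates, dLs_dt=rng.normal(0, 2))
            du = -(d[0] + d[3] + d[6] + d[10])  # implied dU/dt
            assert d[0] + d[3] + d[6] + d[10] + du == pytest.approx(0.0, abs=1e-14)

    def test_step_response_matches_fine_euler_oracle(self):
        """Independent fine-step explicit-Euler integration, dt = 1e-6 s."""
        cb = CrossbridgeParams()
        rates = effective_rates(cb)
        ca, ov = 2.16, thick_filament_overlap(2.2)
        y = WallMechState().kinetic_vector()
        dt, t_end = 1e-6, 0.05
        for _ in range(int(t_end / dt)):
            w = WallMechState.from_kinetic_vector(y, 2.2)
            y = y + dt * crossbridge_derivatives(w, ca, ov, rates)
        euler_p30 = y[6]
        from scipy.integrate import solve_ivp

        def f(t, yy):
            return crossbridge_derivatives(
                WallMechState.from_kinetic_vector(yy, 2.2), ca, ov, rates)

        sol = solve_ivp(f, (0, t_end), WallMechState().kinetic_vector(),
                        method="BDF", rtol=1e-10, atol=1e-13)
        assert sol.y[6, -1] == pytest.approx(euler_p30, rel=1e-4)

    def test_invalid_state_rejected(self):
        w = WallMechState(p1_2=-1e-3)
        with pytest.raises(SarcomereError):
            crossbridge_derivatives(w, 1.0, 1.0, effective_rates(CrossbridgeParams()))


class TestStresses:
    def test_active_stress_zero_state_and_direct_value(self):
        cb = replace(CrossbridgeParams(), k_stiff1=100.0, k_stiff2=100.0, dr=0.01)
        assert active_stress(WallMechState(), 1.0, cb) == 0.0
        w = WallMechState(p2_1=0.01, p3_1=0.01, p3_0=0.2)
        assert active_stress(w, 1.0, cb) == pytest.approx(100 * 0.02 + 100 * 0.01 * 0.2)

    def test_active_stress_linear_in_stiffness(self):
        cb = CrossbridgeParams()
        cb2 = replace(cb, k_stiff1=2 * cb.k_stiff1, k_stiff2=2 * cb.k_stiff2)
        w = WallMechState(p2_1=0.005, p3_1=0.003, p3_0=0.2)
        assert active_stress(w, 0.7, cb2) == pytest.approx(2 * active_stress(w, 0.7, cb))

    def test_passive_stress_slack_and_value(self):
        mf = replace(MyofiberParams(), k_passive=10.0, L_sc0=1.51, gamma=2.0)
        assert passive_stress(1.51, mf) == 0.0
        assert passive_stress(1.2, mf) == 0.0  # no compressive collagen force
        assert passive_stress(2.2, mf) == pytest.approx(10 * 0.69 ** 2)

    def test_hyperoxia_passive_ratio_exactly_two(self):
        mf = MyofiberParams()
        mf_hx = replace(mf, k_passive=2.0 * mf.k_passive)
        for ls in (1.8, 2.0, 2.2, 2.35):
            assert passive_stress(ls, mf_hx) == pytest.approx(
                2.0 * passive_stress(ls, mf), rel=1e-14)

    def test_viscous_stress_odd_symmetry(self):
        assert viscous_stress(0.0, 1.0) == 0.0
        assert viscous_stress(-0.5, 1.0) == -0.5
        assert viscous_stress(-2.0, 0.7) == -viscous_stress(2.0, 0.7)

    def test_force_balance_equilibrium_and_closure(self):
        mf = MyofiberParams()
        w = WallMechState(L_s=2.0)
        dls, s_se = myofiber_force_balance(2.0, w, mf, 0.0, 0.0)
        assert dls == 0.0 and s_se == 0.0
        # closure: sigma_SE - sigma_XB - sigma_pas - sigma_visc == 0 identically
        dls, s_se = myofiber_force_balance(2.1, w, mf, 3.0, 1.0)
        assert s_se - 3.0 - 1.0 - viscous_stress(dls, mf.eta) == pytest.approx(0, abs=1e-12)

    def test_series_element_relaxation_matches_closed_form(self):
        """Linear ODE oracle: L_s -> L_s_wall exponentially at rate K_SE/eta."""
        from scipy.integrate import solve_ivp
        mf = replace(MyofiberParams(), k_passive=1.0, L_sc0=5.0)  # passive off

        def f(t, y):
            w = WallMechState(L_s=y[0])
            dls, _ = myofiber_force_balance(2.2, w, mf, 0.0, 0.0)
            return [dls]

        sol = solve_ivp(f, (0, 0.004), [2.0], method="BDF", rtol=1e-12, atol=1e-14)
        rate = mf.K_SE / mf.eta
        exact = 2.2 - 0.2 * math.exp(-rate * sol.t[-1])
        assert sol.y[0, -1] == pytest.approx(exact, rel=1e-6)

    def test_zero_viscosity_is_singular(self):
        with pytest.raises(SarcomereError):
            replace(MyofiberParams(), eta=0.0)


class TestOverlap:
    def test_plateau_and_limits(self):
        assert thick_filament_overlap(2.17) == 1.0
        assert thick_filament_overlap(0.9) == 0.0
        assert thick_filament_overlap(4.0) == 0.0

    def test_unimodal_on_dense_grid(self):
        ls = np.linspace(0.8, 4.0, 2000)
        ov = np.array([thick_filament_overlap(x) for x in ls])
        assert ov.min() >= 0.0 and ov.max() == 1.0
        d = np.diff(ov)
        first_desc = np.argmax(d < -1e-12)
        assert np.all(d[first_desc:] <= 1e-12)  # never rises again


class TestForcePCa:
    def test_near_zero_force_at_pca7(self, force_pca_pair):
        nx, _ = force_pca_pair
        assert nx.force_kpa[-1] < 0.05 * nx.force_kpa[0]

    def test_monotone_in_calcium(self, force_pca_pair):
        nx, hx = force_pca_pair
        for c in (nx, hx):
            assert np.all(np.diff(c.force_kpa) <= 1e-9)  # non-increasing in pCa

    def test_sigmoidal_single_inflection(self, force_pca_pair):
        nx, _ = force_pca_pair
        d2 = np.diff(nx.force_kpa, 2)
        signs = np.sign(d2[np.abs(d2) > 1e-9 * nx.force_kpa[0]])
        assert (np.diff(signs) != 0).sum() == 1

    def test_integration_matches_steady_solver(self, nominal_nx):
        grid = np.array([4.5, 5.5, 5.9, 6.5])
        cb = nominal_nx.crossbridge_params("RV")
        a = simulate_force_pca(cb, sl=2.2, pca_grid=grid, method="steady")
        b = simulate_force_pca(cb, sl=2.2, pca_grid=grid, method="integrate")
        assert np.allclose(a.force_kpa, b.force_kpa, rtol=1e-5)

    def test_hx_raises_both_pca50_and_fmax(self, force_pca_pair):
        nx, hx = force_pca_pair
        p0, f0 = pca_curve_summary(nx)
        p1, f1 = pca_curve_summary(hx)
        assert p1 > p0 and f1 > f0

    def test_summary_recovers_hill_curve(self):
        """Closed-form Hill oracle with pCa50 = 5.8, n = 4."""
        pca = np.linspace(4.5, 7.0, 26)
        ca = 10.0 ** (-pca)
        ca50 = 10.0 ** (-5.8)
        force = 40.0 * ca ** 4 / (ca ** 4 + ca50 ** 4)
        pca50, fmax = pca_curve_summary(ForcePCaCurve(pca, force, 2.2))
        assert pca50 == pytest.approx(5.8, abs=5e-3)
        # scaling the curve doubles Fmax and leaves pCa50 unchanged
        p2, f2 = pca_curve_summary(ForcePCaCurve(pca, 2 * force, 2.2))
        assert f2 == pytest.approx(2 * fmax)
        assert p2 == pytest.approx(pca50, abs=1e-12)

    def test_unbracketed_half_max_rejected(self):
        pca = np.linspace(4.5, 5.0, 6)
        with pytest.raises(SarcomereError):
            pca_curve_summary(ForcePCaCurve(pca, np.full(6, 10.0), 2.2))

    def test_equal_and_opposite_ca_sensitivity(self, nominal_nx):
        """Proportional k_on increase and k_off decrease shift pCa50 identically."""
        cb = nominal_nx.crossbridge_params("RV")
        up = replace(cb, k_on=1.25 * cb.k_on)
        dn = replace(cb, k_off=cb.k_off / 1.25)
        p_up, _ = pca_curve_summary(simulate_force_pca(up))
        p_dn, _ = pca_curve_summary(simulate_force_pca(dn))
        assert p_up == pytest.approx(p_dn, abs=2e-3)


#: Table of directional force-pCa effects: (parameter, direction,
#: expected sign of dFmax, expected sign of dpCa50); None = unconstrained.
DIRECTION_CASES = [
    ("k_stiff2", "up", +1, None),
    ("dr", "up", +1, None),
    ("k_1", "up", +1, None),
    ("k_on", "up", None, +1),
    ("k_off", "down", None, +1),
    ("k_a", "up", None, +1),
    ("k_3", "down", +1, +1),
    ("K_D", "down", +1, +1),
    ("K_T", "up", +1, +1),
    ("ATP", "down", +1, +1),
    ("ADP", "up", +1, +1),
]


@pytest.mark.parametrize("param,direction,want_fmax,want_pca50", DIRECTION_CASES)
def test_parameter_direction_screen(param, direction, want_fmax, want_pca50):
    d_fmax, d_pca50 = parameter_direction_screen(param, direction)
    if want_fmax is not None:
        assert d_fmax == want_fmax
    if want_pca50 is not None:
        assert d_pca50 == want_pca50


def test_direction_screen_rejects_unknown_parameter():
    with pytest.raises(SarcomereError):
        parameter_direction_screen("k_nonexistent", "up")


@settings(max_examples=25, deadline=None)
@given(ca=st.floats(0.05, 30.0), kon=st.floats(10.0, 200.0))
def test_calcium_gate_is_cooperative_power_law(ca, kon):
    g = calcium_gate(ca, kon)
    assert g == pytest.approx(kon * ca * (ca / CA_GATE_REF) ** (HILL_EXPONENT - 1),
                              rel=1e-12)


@settings(max_examples=20, deadline=None)
@given(ca=st.floats(0.05, 30.0), ov=st.floats(0.05, 1.0))
def test_steady_fractions_conserve_and_bound(ca, ov):
    rates = effective_rates(CrossbridgeParams())
    a1, a2, a3, u, usr, nnp = steady_state_fractions(ca, ov, rates)
    total = a1 + a2 + a3 + u + usr
    assert total == pytest.approx(1.0, abs=1e-12)
    for f in (a1, a2, a3, u, usr, nnp):
        assert -1e-12 <= f <= 1.0 + 1e-12
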