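"""TriSeg geometry, circulation elements, and the closed-loop steady state."""

import math

import numpy as np
import pytest

from cardioscale import _core
from cardioscale.heart import (CirculationParams, FullState, HeartError, TriSegParams,
                               assemble_rhs, compartment_pressure, extract_cycle,
                               initial_state, run_to_steady_state,
                               solve_triseg_geometry, valve_flow,
                               ventricular_pressures, volume_extreme_octet)
from cardioscale.sarcomere import (WallMechState, active_stress, calcium_transient,
                                   crossbridge_derivatives, effective_rates,
                                   myofiber_force_balance, passive_stress,
                                   thick_filament_overlap)
from cardioscale.units import MMHG_PER_KPA, UL_PER_ML


@pytest.fixture(scope="module")
def tp(nominal_nx):
    return TriSegParams.from_parameter_set(nominal_nx)


class TestTriSegGeometry:
    def test_cap_volume_identity(self, tp):
        geom = solve_triseg_geometry(0.044, 0.052, (3.0, 2.5, 3.5), tp)
        from cardioscale.heart import _cap_volume
        vm_lv = _cap_volume(geom.x_m_SEP, geom.y_m) - _cap_volume(geom.x_m_LV, geom.y_m)
        vm_rv = _cap_volume(geom.x_m_RV, geom.y_m) - _cap_volume(geom.x_m_SEP, geom.y_m)
        assert vm_lv - 0.5 * (tp.V_w_LV + tp.V_w_SEP) == pytest.approx(0.044, abs=1e-8)
        assert vm_rv - 0.5 * (tp.V_w_RV + tp.V_w_SEP) == pytest.approx(0.052, abs=1e-8)

    def test_geometric_similarity_scaling(self, tp):
        s = 1.3
        geom1 = solve_triseg_geometry(0.044, 0.052, (3.0, 2.5, 3.5), tp)
        tp2 = TriSegParams(tp.A_m_ref_LV * s ** 2, tp.A_m_ref_SEP * s ** 2,
                           tp.A_m_ref_RV * s ** 2, tp.V_w_LV * s ** 3,
                           tp.V_w_SEP * s ** 3, tp.V_w_RV * s ** 3)
        geom2 = solve_triseg_geometry(0.044 * s ** 3, 0.052 * s ** 3,
                                      (3.0, 2.5, 3.5), tp2,
                                      guess=[geom1.x_m_LV * s, geom1.x_m_SEP * s,
                                             geom1.x_m_RV * s, geom1.y_m * s])
        assert geom2.x_m_LV == pytest.approx(s * geom1.x_m_LV, rel=1e-6)
        assert geom2.y_m == pytest.approx(s * geom1.y_m, rel=1e-6)

    def test_mirror_symmetric_ventricles_flat_septum(self):
        """Symmetric-by-construction root has x_SEP = 0; the solver finds it."""
        vw, aref = 0.08, 0.9
        tp = TriSegParams(aref, 0.45, aref, vw, 0.04, vw)
        sigma = 4.0
        # solve for the septal stress that balances the junction at x_SEP = 0
        from cardioscale.heart import _cap_volume, _tension_components, _wall_quantities
        from scipy.optimize import brentq

        def radial_imbalance(sig_sep, x, y):
            a_m, _, z, _ = _wall_quantities(x, y, vw, aref)
            _, ty_lv = _tension_components(x, y, sigma, vw, a_m, z)
            a_s, _, z_s, _ = _wall_quantities(0.0, y, 0.04, 0.45)
            _, ty_sep = _tension_components(0.0, y, sig_sep, 0.04, a_s, z_s)
            return 2 * ty_lv + ty_sep

        # symmetric cavity volume fixes (x, y) through the cap identity
        v_cav = 0.05
        vm = v_cav + 0.5 * (vw + 0.04)

        def xy_from(yv):
            x = brentq(lambda xx: _cap_volume(xx, yv) - vm, 1e-4, 2.0)
            return x

        y0 = 0.32
        x0 = xy_from(y0)
        sig_sep = brentq(lambda s: radial_imbalance(s, x0, y0), -50, 50)
        geom = solve_triseg_geometry(v_cav, v_cav, (sigma, sig_sep, sigma), tp,
                                     guess=[-x0 * 1.05, 0.02, x0 * 0.95, y0 * 1.02])
        assert abs(geom.x_m_SEP) < 1e-6
        assert geom.C_m["SEP"] == pytest.approx(0.0, abs=1e-5)
        p_lv, p_rv = ventricular_pressures(geom, (sigma, sig_sep, sigma), tp)
        assert p_lv == pytest.approx(p_rv, rel=1e-6)

    def test_pressures_zero_stress_and_linearity(self, tp):
        geom = solve_triseg_geometry(0.044, 0.052, (3.0, 2.5, 3.5), tp)
        p0 = ventricular_pressures(geom, (0.0, 0.0, 0.0), tp)
        assert p0 == (0.0, 0.0)
        p1 = ventricular_pressures(geom, (3.0, 2.5, 3.5), tp)
        p2 = ventricular_pressures(geom, (6.0, 5.0, 7.0), tp)
        assert p2[0] == pytest.approx(2 * p1[0], rel=1e-12)
        assert p2[1] == pytest.approx(2 * p1[1], rel=1e-12)

    def test_single_sphere_degenerate_laplace(self):
        """Thin-wall Laplace oracle: P = 2 sigma h / r within 2 % for small h/r."""
        # nearly-closed RV cap (tiny junction) approximates a full sphere
        r, h, sigma = 0.4, 0.008, 5.0
        v_w = 4 * math.pi * r ** 2 * h
        v_cav = 4 / 3 * math.pi * r ** 3
        a_ref = 4 * math.pi * r ** 2
        from cardioscale.heart import _tension_components, _wall_quantities
        # place the junction at a small polar angle: x spans almost 2r
        y = 0.08
        x = r + math.sqrt(r * r - y * y)
        a_m, _, z, _ = _wall_quantities(x, y, v_w, a_ref)
        tx, _ = _tension_components(x, y, sigma, v_w, a_m, z)
        p = 2 * tx / y * MMHG_PER_KPA
        p_laplace = 2 * sigma * h / r * MMHG_PER_KPA
        assert p == pytest.approx(p_laplace, rel=0.02)

    def test_nonconvergence_signalled(self, tp):
        with pytest.raises(HeartError):
            solve_triseg_geometry(0.044, 0.052, (3.0, 2.5, 3.5), tp,
                                  guess=[5.0, -5.0, 5.0, 1e-6])


class TestCirculationElements:
    def test_compartment_pressure(self):
        assert compartment_pressure(1.0, 0.04, 1.0) == 0.0
        assert compartment_pressure(26.0, 1.0, 1.0) == 25.0
        assert compartment_pressure(2.0, 0.5, 1.0) == 2 * compartment_pressure(2.0, 1.0, 1.0)

    def test_valve_flow_diode(self):
        assert valve_flow(5.0, 10.0, 2.0) == 0.0
        assert valve_flow(15.0, 5.0, 2.0) == 5.0
        assert valve_flow(1e-9, 0.0, 2.0) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(HeartError):
            valve_flow(1.0, 0.0, 0.0)

    def test_valve_flow_smooth_variant_continuous(self):
        w = 0.01
        lo = valve_flow(-1e-6, 0.0, 1.0, smooth=w)
        hi = valve_flow(+1e-6, 0.0, 1.0, smooth=w)
        assert hi - lo == pytest.approx(0.0, abs=1e-5)
        assert valve_flow(5.0, 0.0, 1.0, smooth=w) == pytest.approx(5.0, rel=1e-4)


class TestFullState:
    def test_state_vector_length_is_46(self, nominal_nx):
        y0 = initial_state(nominal_nx)
        assert y0.shape == (46,)
        fs = FullState(y0)
        assert fs.volumes.shape == (6,)
        fs.validate(v_total=nominal_nx.V_total)

    def test_initial_volume_conservation(self, nominal_nx):
        y0 = initial_state(nominal_nx)
        assert y0[40:46].sum() == pytest.approx(nominal_nx.V_total, rel=1e-12)

    def test_bad_length_rejected(self):
        with pytest.raises(HeartError):
            FullState(np.zeros(45))


class TestAssembleRHS:
    def test_closed_loop_volume_derivative_sums_to_zero(self, nominal_nx):
        y0 = initial_state(nominal_nx)
        dy = assemble_rhs(y0, 0.0, nominal_nx)
        assert dy[40:46].sum() == pytest.approx(0.0, abs=1e-14)

    def test_rhs_matches_hand_assembled_reference(self, nominal_nx):
        """Independent assembly oracle built from the public operations."""
        p = nominal_nx
        y = initial_state(p)
        # make the state generic: some crossbridge occupancy and flow gradients
        y[0], y[3], y[6] = 0.05, 0.04, 0.08
        y[9], y[10] = 0.5, 0.2
        y[11 + 6], y[22 + 6] = 0.06, 0.07
        t = 0.03
        dy = assemble_rhs(y, t, p)

        ca = calcium_transient(t % p.T, p.calcium_schedule())
        tp = TriSegParams.from_parameter_set(p)
        # solve the self-consistent geometry (stress depends on geometry)
        # with an independent root-finder over the four unknowns
        from scipy.optimize import root as sp_root
        from cardioscale.heart import _cap_volume, _tension_components, _wall_quantities
        vw = [tp.V_w_LV, tp.V_w_SEP, tp.V_w_RV]
        vm_lv = y[40] + 0.5 * (vw[0] + vw[1])
        vm_rv = y[41] + 0.5 * (vw[2] + vw[1])

        def sc_residuals(g):
            xs, ym = g[:3], g[3]
            tx = ty = 0.0
            for i in range(3):
                a_m, _, z, _ = _wall_quantities(xs[i], ym, vw[i],
                                                [tp.A_m_ref_LV, tp.A_m_ref_SEP,
                                                 tp.A_m_ref_RV][i])
                txi, tyi = _tension_components(xs[i], ym, _se_stresses_at(g, y, p)[i],
                                               vw[i], a_m, z)
                tx += txi
                ty += tyi
            return [_cap_volume(xs[1], ym) - _cap_volume(xs[0], ym) - vm_lv,
                    _cap_volume(xs[2], ym) - _cap_volume(xs[1], ym) - vm_rv,
                    tx, ty]

        sol = sp_root(sc_residuals, y[36:40], method="hybr",
                      options={"xtol": 1e-13})
        assert sol.success
        g = sol.x
        sig = _se_stresses_at(g, y, p)
        geom = solve_triseg_geometry(y[40], y[41], sig, tp, guess=g,
                                     l_s_ref=p["L_s_ref"])
        p_lv, p_rv = ventricular_pressures(geom, sig, tp)
        circ = CirculationParams.from_parameter_set(p)
        p_sa = compartment_pressure(y[42], circ.C_SA, p.V_un["SA"])
        p_sv = compartment_pressure(y[43], circ.C_SV, p.V_un["SV"])
        p_pa = compartment_pressure(y[44], circ.C_PA, p.V_un["PA"])
        p_pv = compartment_pressure(y[45], circ.C_PV, p.V_un["PV"])
        w = 0.02  # the core's soft-plus diode width
        q_m = valve_flow(p_pv, p_lv, circ.R_m, smooth=w)
        q_a = valve_flow(p_lv, p_sa, circ.R_a, smooth=w) * _avail(y[40])
        q_sa = (p_sa - p_sv) / circ.R_SA
        q_t = valve_flow(p_sv, p_rv, circ.R_t, smooth=w)
        q_p = valve_flow(p_rv, p_pa, circ.R_p, smooth=w) * _avail(y[41])
        q_pa = (p_pa - p_pv) / circ.R_PA
        expect_dv = [q_m - q_a, q_t - q_p, q_a - q_sa, q_sa - q_t, q_p - q_pa,
                     q_pa - q_m]
        # agreement limited by the two independent geometry root-finders
        assert np.allclose(dy[40:46], expect_dv, atol=1e-7)

        for i, wall in enumerate(("LV", "SEP", "RV")):
            ws = WallMechState.from_kinetic_vector(y[11 * i:11 * i + 11], y[33 + i])
            ov = thick_filament_overlap(ws.L_s)
            cb = p.crossbridge_params(wall)
            mf = p.myofiber_params(wall)
            s_xb = active_stress(ws, ov, cb)
            s_pas = passive_stress(ws.L_s, mf)
            dls, _ = myofiber_force_balance(geom.L_s_wall[wall], ws, mf, s_xb, s_pas)
            assert dy[33 + i] == pytest.approx(dls, rel=1e-7, abs=1e-9)
            dk = crossbridge_derivatives(ws, ca, ov, effective_rates(cb), dls)
            assert np.allclose(dy[11 * i:11 * i + 11], dk, rtol=1e-7, atol=1e-10)


def _avail(v):
    return v * v / (v * v + 4.0e-6)


def _se_stresses_at(g, y, p):
    """Load-bearing wall stresses at geometry ``g`` (soft tensile floor)."""
    pv = p.core_vector()
    return [_core._wall_stress(i, g[i], g[3], y[33 + i], pv)[0] for i in range(3)]


class TestSteadyState:
    def test_stroke_volumes_match_within_one_percent(self, nx_cycle):
        sv_lv = nx_cycle.stroke_volume("LV")
        sv_rv = nx_cycle.stroke_volume("RV")
        assert abs(sv_lv - sv_rv) / sv_lv < 0.01

    def test_blood_volume_conserved(self, nx_cycle, nominal_nx):
        total = (nx_cycle.V_LV + nx_cycle.V_RV) / UL_PER_ML
        # vascular volumes are not in the CycleSeries; check the final state
        assert nx_cycle.final_state[40:46].sum() == pytest.approx(
            nominal_nx.V_total, abs=1e-6 * nominal_nx.V_total)

    def test_valve_flows_nonnegative(self, nx_cycle):
        for q in ("Q_m", "Q_a", "Q_t", "Q_p"):
            assert np.all(nx_cycle.flows[q] >= -1e-12)

    def test_pressure_ordering(self, nx_cycle):
        assert nx_cycle.P_SA.mean() > nx_cycle.P_SV.mean()
        assert nx_cycle.P_PA.mean() > nx_cycle.P_PV.mean()

    def test_mpap_between_pa_extremes(self, nx_cycle):
        m = nx_cycle.P_PA.mean()
        assert nx_cycle.P_PA.min() < m < nx_cycle.P_PA.max()

    def test_physiological_operating_point(self, nx_cycle):
        o = nx_cycle.octet
        assert 50 < o["ESP_LV"] < 90
        assert 15 < o["ESP_RV"] < 35
        assert 20 < nx_cycle.stroke_volume("LV") < 40

    def test_preload_response(self, nominal_nx, nx_cycle):
        """Frank-Starling direction: +10 % blood volume raises both EDVs."""
        p = nominal_nx.copy()
        p.V_total = 1.10 * p.V_total
        extra = p.V_total - nominal_nx.V_total
        y0 = nx_cycle.final_state.copy()
        y0[43] += extra  # park the added volume in the systemic veins
        c2 = run_to_steady_state(p, tol=2e-3, rtol=1e-6, y0=y0)
        assert c2.octet["EDV_LV"] > nx_cycle.octet["EDV_LV"]
        assert c2.octet["EDV_RV"] > nx_cycle.octet["EDV_RV"]

    def test_afterload_direction(self, nominal_nx, nx_cycle):
        """Doubling pulmonary resistance raises RV end-systolic pressure."""
        p = nominal_nx.copy()
        p["R_PA"] = 2.0 * p["R_PA"]
        c2 = run_to_steady_state(p, tol=2e-3, rtol=1e-6, y0=nx_cycle.final_state)
        assert c2.octet["ESP_RV"] > nx_cycle.octet["ESP_RV"]


class TestExtractCycle:
    def test_constant_signal_resamples_constant(self, nominal_nx):
        class FakeSol:
            def __call__(self, tg):
                return np.tile(initial_state(nominal_nx)[:, None], (1, len(tg)))
        c = extract_cycle(FakeSol(), 0.177, nominal_nx, n=50)
        assert np.allclose(c.V_LV, c.V_LV[0])
        assert len(c.t) == 50
        assert c.t[0] == 0.0 and c.t[-1] < 0.177  # half-open grid

    def test_resampled_sine_quadrature(self):
        """Quadrature oracle: a resampled sine integrates to ~0 at O(N^-2)."""
        n = 50
        t = np.arange(n) / n
        s = np.sin(2 * np.pi * t)
        assert abs(np.trapezoid(np.append(s, s[0]), dx=1 / n)) < 1.0 / n ** 2

    def test_octet_plateau_reads(self):
        v = np.array([10.0, 9.99, 5.0, 1.0, 1.004, 3.0])
        p = np.array([2.0, 30.0, 60.0, 55.0, 20.0, 5.0])
        o = volume_extreme_octet(v, p, v, p)
        assert o["EDV_LV"] == 10.0 and o["ESV_LV"] == 1.0
        assert o["EDP_LV"] == 2.0    # min pressure on the ED plateau
        assert o["ESP_LV"] == 55.0   # max pressure on the ES plateau
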