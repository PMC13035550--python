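"""Numba-compiled right-hand side of the 46-state heart + circulation system.

State layout (length 46)::

    y[0:33]   three 11-entry wall kinetic blocks (LV, SEP, RV):
              p1_0 p1_1 p1_2 p2_0 p2_1 p2_2 p3_0 p3_1 p3_2 N_np U_SR
    y[33:36]  contractile sarcomere lengths L_s (um), LV SEP RV
    y[36:40]  spherical-cap geometry x_LV, x_SEP, x_RV, y_m (cm)
    y[40:46]  compartment volumes V_LV V_RV V_SA V_SV V_PA V_PV (mL)

Packed parameter vector layout (length 52), see ``PV_*`` index constants.

The four geometric unknowns satisfy two cavity-volume constraints and the
radial/axial midwall tension balances at the junction ring.  Each RHS
evaluation solves that 4x4 algebraic system by a damped Newton iteration
warm-started from the geometry states, then relaxes the states toward the
solved root on a fast time scale, so the hemodynamic quantities always use
the exact root while the integrator sees smooth dynamics.
"""

import numpy as np
from numba import njit

# --- packed parameter indices --------------------------------------------
PV_KA, PV_KD, PV_K1E, PV_KM1E, PV_KADP, PV_K3E, PV_KSR, PV_KMSR, PV_KON, PV_DR = range(10)
PV_KOFF = 10       # 10..12 per wall
PV_KSTIFF1 = 13    # 13..15
PV_KSTIFF2 = 16    # 16..18
PV_KPASSIVE = 19   # 19..21
PV_GAMMA, PV_LSC0, PV_ETA, PV_KSE, PV_LSREF = 22, 23, 24, 25, 26
PV_CADIA, PV_CAAMP, PV_TS, PV_TR, PV_T = 27, 28, 29, 30, 31
PV_AMREF = 32      # 32..34
PV_VW = 35         # 35..37
PV_CSA, PV_CSV, PV_CPA, PV_CPV = 38, 39, 40, 41
PV_RSA, PV_RPA, PV_RM, PV_RA, PV_RT, PV_RP = 42, 43, 44, 45, 46, 47
PV_VUN = 48        # 48..51: SA SV PA PV
PV_LEN = 52

NSTATE = 46

# structural constants (match cardioscale.sarcomere)
_HILL = 4.0
_CAREF = 1.0
_OV_LO, _OV_PLO, _OV_PHI, _OV_HI = 1.60, 2.05, 2.30, 3.60
_MMHG_PER_KPA = 7.50061682704
_TAU_GEOM = 1.0e-3  # s, relaxation of geometry states onto the solved root
_VALVE_W = 0.02     # mmHg, soft-plus smoothing width of the valve diodes
_PI = np.pi


@njit(cache=True)
def _diode(dp, r):
    """Soft-plus smoothed ideal-diode flow (mL/s)."""
    if dp > 30.0 * _VALVE_W:
        return dp / r
    return _VALVE_W * np.log1p(np.exp(dp / _VALVE_W)) / r


@njit(cache=True)
def _avail(v):
    """Smooth outflow gate: a near-empty cavity (walls coapting) cannot eject.

    ~1 above ~10 uL and ~0.5 at 2 uL; physical trajectories sit at 1.
    """
    return v * v / (v * v + 4.0e-6)


@njit(cache=True)
def _overlap(ls):
    if ls <= _OV_LO or ls >= _OV_HI:
        return 0.0
    if ls < _OV_PLO:
        return (ls - _OV_LO) / (_OV_PLO - _OV_LO)
    if ls <= _OV_PHI:
        return 1.0
    return (_OV_HI - ls) / (_OV_HI - _OV_PHI)


@njit(cache=True)
def _ca_transient(t, pv):
    T = pv[PV_T]
    tt = t - np.floor(t / T) * T
    ts = pv[PV_TS] * T
    tr = pv[PV_TR] * T
    if tt < ts:
        return pv[PV_CADIA] + pv[PV_CAAMP] * 0.5 * (1.0 - np.cos(_PI * tt / ts))
    if tt <= ts + tr:
        return pv[PV_CADIA] + pv[PV_CAAMP] * 0.5 * (1.0 + np.cos(_PI * (tt - ts) / tr))
    return pv[PV_CADIA]


@njit(cache=True)
def _vcap(x, y):
    """Signed spherical-cap volume displaced past the junction plane (mL)."""
    return (_PI / 6.0) * x * (x * x + 3.0 * y * y)


_SIGMA_W = 0.1  # kPa, width of the smooth tensile floor on wall stress


@njit(cache=True)
def _wall_stress(iw, x, y, ls, pv):
    """Load-bearing fiber stress (kPa) of wall ``iw`` at cap (x, y).

    The series element sets the stress, floored smoothly at zero: a
    transiently slack wall wrinkles rather than supporting compression,
    which also keeps the junction tension balance away from the
    septal snap-through regime.  Returns (sigma, Am, z) where Am is the
    midwall area (cm^2) and z the thick-wall correction ratio.
    """
    r2 = x * x + y * y
    am = _PI * r2
    cm = 2.0 * x / r2
    vw = pv[PV_VW + iw]
    z = 3.0 * cm * vw / (2.0 * am)
    eps = 0.5 * np.log(am / pv[PV_AMREF + iw]) - z * z / 12.0 - 0.019 * z ** 4
    lsw = pv[PV_LSREF] * np.exp(eps)
    sigma = pv[PV_KSE] * (lsw - ls)
    if sigma < 30.0 * _SIGMA_W:
        sigma = _SIGMA_W * np.log1p(np.exp(sigma / _SIGMA_W))
    return sigma, am, z


@njit(cache=True)
def _triseg_residuals(g, vlv, vrv, ls3, pv, out):
    xlv, xsep, xrv, y = g[0], g[1], g[2], g[3]
    if y <= 0.0:
        for i in range(4):
            out[i] = 1.0e6
        return
    vw_lv = pv[PV_VW + 0]
    vw_sep = pv[PV_VW + 1]
    vw_rv = pv[PV_VW + 2]
    vm_lv = vlv + 0.5 * (vw_lv + vw_sep)
    vm_rv = vrv + 0.5 * (vw_rv + vw_sep)
    vsc = vm_lv + vm_rv

    tx_sum = 0.0
    ty_sum = 0.0
    # absolute floor on the tension scale: as all wall tensions pass through
    # zero the junction balance degenerates, and the floored scaling lets the
    # Newton iteration accept the (continuous) warm start instead of chasing
    # an ill-determined root
    tsc = 1.0e-3
    for iw in range(3):
        x = g[iw]
        r2 = x * x + y * y
        sigma, am, z = _wall_stress(iw, x, y, ls3[iw], pv)
        tm = pv[PV_VW + iw] * sigma * (1.0 + z * z / 3.0 + z ** 4 / 5.0) / am
        tx = tm * 2.0 * x * y / r2
        ty = tm * (y * y - x * x) / r2
        tx_sum += tx
        ty_sum += ty
        if np.abs(tm) > tsc:
            tsc = np.abs(tm)
    out[0] = (_vcap(xsep, y) - _vcap(xlv, y) - vm_lv) / vsc
    out[1] = (_vcap(xrv, y) - _vcap(xsep, y) - vm_rv) / vsc
    out[2] = tx_sum / tsc
    out[3] = ty_sum / tsc


@njit(cache=True)
def _solve4(a, b):
    """Solve a 4x4 system by Gaussian elimination with partial pivoting.

    Returns (x, ok); ok is False when a pivot is numerically zero.
    """
    m = a.copy()
    x = b.copy()
    for k in range(4):
        piv = k
        big = np.abs(m[k, k])
        for i in range(k + 1, 4):
            if np.abs(m[i, k]) > big:
                big = np.abs(m[i, k])
                piv = i
        if big < 1.0e-14:
            return x, False
        if piv != k:
            for j in range(4):
                tmp = m[k, j]
                m[k, j] = m[piv, j]
                m[piv, j] = tmp
            tmp = x[k]
            x[k] = x[piv]
            x[piv] = tmp
        for i in range(k + 1, 4):
            f = m[i, k] / m[k, k]
            for j in range(k, 4):
                m[i, j] -= f * m[k, j]
            x[i] -= f * x[k]
    for i in range(3, -1, -1):
        s = x[i]
        for j in range(i + 1, 4):
            s -= m[i, j] * x[j]
        x[i] = s / m[i, i]
    return x, True


@njit(cache=True)
def _solve_triseg(g0, vlv, vrv, ls3, pv, tol, max_iter):
    """Damped Newton solve of the TriSeg algebra.  Returns (g, ok)."""
    g = g0.copy()
    r = np.empty(4)
    rp = np.empty(4)
    jac = np.empty((4, 4))
    _triseg_residuals(g, vlv, vrv, ls3, pv, r)
    nrm = np.sqrt(np.sum(r * r))
    for _ in range(max_iter):
        if nrm < tol:
            return g, True
        for j in range(4):
            h = 1.0e-7 * max(np.abs(g[j]), 1.0e-3)
            gs = g[j]
            g[j] = gs + h
            _triseg_residuals(g, vlv, vrv, ls3, pv, rp)
            g[j] = gs
            for i in range(4):
                jac[i, j] = (rp[i] - r[i]) / h
        step, solvable = _solve4(jac, r)
        if not solvable:
            return g, False
        # trust-region cap: near-degenerate (low-tension) states produce
        # ill-conditioned Newton directions; capping each component keeps
        # the iteration in the warm-start basin instead of a distant root
        cap = 1.0
        for j in range(4):
            lim = 0.10 * max(np.abs(g[j]), 0.05)
            if np.abs(step[j]) * cap > lim:
                cap = lim / np.abs(step[j])
        if cap < 1.0:
            for j in range(4):
                step[j] *= cap
        lam = 1.0
        accepted = False
        for _k in range(6):
            gn = g - lam * step
            _triseg_residuals(gn, vlv, vrv, ls3, pv, rp)
            nn = np.sqrt(np.sum(rp * rp))
            if np.isfinite(nn) and nn < nrm:
                g = gn
                for i in range(4):
                    r[i] = rp[i]
                nrm = nn
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            return g, nrm < tol * 10.0
    return g, nrm < tol


@njit(cache=True)
def _pressures_mmhg(g, ls3, pv):
    """(P_LV, P_RV) in mmHg from the solved geometry and wall stresses."""
    y = g[3]
    # LV free wall
    xlv = g[0]
    r2 = xlv * xlv + y * y
    s_lv, am_lv, z_lv = _wall_stress(0, xlv, y, ls3[0], pv)
    tm = pv[PV_VW + 0] * s_lv * (1.0 + z_lv * z_lv / 3.0 + z_lv ** 4 / 5.0) / am_lv
    tx_lv = tm * 2.0 * xlv * y / r2
    # RV free wall
    xrv = g[2]
    r2 = xrv * xrv + y * y
    s_rv, am_rv, z_rv = _wall_stress(2, xrv, y, ls3[2], pv)
    tm = pv[PV_VW + 2] * s_rv * (1.0 + z_rv * z_rv / 3.0 + z_rv ** 4 / 5.0) / am_rv
    tx_rv = tm * 2.0 * xrv * y / r2
    p_lv = -2.0 * tx_lv / y * _MMHG_PER_KPA
    p_rv = 2.0 * tx_rv / y * _MMHG_PER_KPA
    return p_lv, p_rv


@njit(cache=True)
def _wall_ls_wall(iw, g, pv):
    """Midwall-strain-implied sarcomere length of wall ``iw`` (um)."""
    x = g[iw]
    y = g[3]
    r2 = x * x + y * y
    am = _PI * r2
    cm = 2.0 * x / r2
    z = 3.0 * cm * pv[PV_VW + iw] / (2.0 * am)
    eps = 0.5 * np.log(am / pv[PV_AMREF + iw]) - z * z / 12.0 - 0.019 * z ** 4
    return pv[PV_LSREF] * np.exp(eps)


@njit(cache=True)
def rhs(t, y, pv):
    """Time derivative of the full 46-state vector."""
    dy = np.zeros(NSTATE)
    ls3 = y[33:36]
    # floor at 2 uL keeps the cap algebra solvable at wild trial states of
    # the implicit integrator; physical trajectories never reach the floor
    vlv = max(y[40], 2.0e-3)
    vrv = max(y[41], 2.0e-3)

    g, ok = _solve_triseg(y[36:40].copy(), vlv, vrv, ls3, pv, 1.0e-11, 30)
    if not ok:
        # cold restart from a volume-based heuristic before giving up
        vm_lv = vlv + 0.5 * (pv[PV_VW + 0] + pv[PV_VW + 1])
        vm_rv = vrv + 0.5 * (pv[PV_VW + 2] + pv[PV_VW + 1])
        r_lv = (3.0 * vm_lv / (2.0 * _PI)) ** (1.0 / 3.0)
        r_rv = (3.0 * vm_rv / (2.0 * _PI)) ** (1.0 / 3.0)
        g0 = np.empty(4)
        g0[0] = -r_lv
        g0[1] = 0.2 * r_rv
        g0[2] = r_rv
        g0[3] = 0.9 * max(r_lv, r_rv)
        g2, ok2 = _solve_triseg(g0, vlv, vrv, ls3, pv, 1.0e-11, 60)
        if ok2:
            g, ok = g2, True
    # if the algebra cannot be solved at this (typically wild trial) state,
    # proceed with the best-effort geometry: the derivatives stay finite and
    # the integrator's error control rejects the step on accuracy grounds

    p_lv, p_rv = _pressures_mmhg(g, ls3, pv)
    p_sa = (y[42] - pv[PV_VUN + 0]) / pv[PV_CSA]
    p_sv = (y[43] - pv[PV_VUN + 1]) / pv[PV_CSV]
    p_pa = (y[44] - pv[PV_VUN + 2]) / pv[PV_CPA]
    p_pv = (y[45] - pv[PV_VUN + 3]) / pv[PV_CPV]

    q_m = _diode(p_pv - p_lv, pv[PV_RM])
    q_a = _diode(p_lv - p_sa, pv[PV_RA]) * _avail(y[40])
    q_sa = (p_sa - p_sv) / pv[PV_RSA]
    q_t = _diode(p_sv - p_rv, pv[PV_RT])
    q_p = _diode(p_rv - p_pa, pv[PV_RP]) * _avail(y[41])
    q_pa = (p_pa - p_pv) / pv[PV_RPA]

    dy[40] = q_m - q_a
    dy[41] = q_t - q_p
    dy[42] = q_a - q_sa
    dy[43] = q_sa - q_t
    dy[44] = q_p - q_pa
    dy[45] = q_pa - q_m

    ca = _ca_transient(t, pv)
    gate = pv[PV_KON] * ca * (ca / _CAREF) ** (_HILL - 1.0)

    for iw in range(3):
        b = 11 * iw
        p10, p11, p12 = y[b], y[b + 1], y[b + 2]
        p20, p21, p22 = y[b + 3], y[b + 4], y[b + 5]
        p30, p31, p32 = y[b + 6], y[b + 7], y[b + 8]
        nnp, usr = y[b + 9], y[b + 10]
        ls = ls3[iw]

        ov = _overlap(ls)
        s_xb = ov * (pv[PV_KSTIFF1 + iw] * (p21 + p31)
                     + pv[PV_KSTIFF2 + iw] * pv[PV_DR] * p30)
        ext = ls - pv[PV_LSC0]
        s_pas = pv[PV_KPASSIVE + iw] * ext ** pv[PV_GAMMA] if ext > 0.0 else 0.0
        lsw = _wall_ls_wall(iw, g, pv)
        s_se = pv[PV_KSE] * (lsw - ls)
        dls = (s_se - s_xb - s_pas) / pv[PV_ETA]
        dy[33 + iw] = dls
        v = 0.5 * dls

        u = 1.0 - p10 - p20 - p30 - usr
        perm = 1.0 - nnp
        att = pv[PV_KA] * ov * u * perm
        a1out = pv[PV_KD] + pv[PV_K1E]
        a2out = pv[PV_KM1E] + pv[PV_KADP]
        k1e = pv[PV_K1E]
        km1e = pv[PV_KM1E]
        kadp = pv[PV_KADP]
        k3e = pv[PV_K3E]

        dy[b] = att - a1out * p10 + km1e * p20
        dy[b + 1] = -a1out * p11 + km1e * p21 + v * p10
        dy[b + 2] = -a1out * p12 + km1e * p22 + 2.0 * v * p11
        dy[b + 3] = k1e * p10 - a2out * p20
        dy[b + 4] = k1e * p11 - a2out * p21 + v * p20
        dy[b + 5] = k1e * p12 - a2out * p22 + 2.0 * v * p21
        dy[b + 6] = kadp * p20 - k3e * p30
        dy[b + 7] = kadp * p21 - k3e * p31 + v * p30
        dy[b + 8] = kadp * p22 - k3e * p32 + 2.0 * v * p31
        dy[b + 9] = pv[PV_KOFF + iw] * (1.0 - nnp) - gate * nnp
        dy[b + 10] = pv[PV_KSR] * u - pv[PV_KMSR] * usr

    for i in range(4):
        dy[36 + i] = (g[i] - y[36 + i]) / _TAU_GEOM
    return dy


@njit(cache=True)
def fd_jacobian(t, y, pv):
    """Forward-difference Jacobian of :func:`rhs` for the stiff integrator."""
    f0 = rhs(t, y, pv)
    jac = np.empty((NSTATE, NSTATE))
    yp = y.copy()
    for j in range(NSTATE):
        # step floor keeps the difference well above roundoff for the
        # small-magnitude moment states
        h = 1.0e-6 * max(np.abs(y[j]), 1.0e-2)
        yp[j] = y[j] + h
        fj = rhs(t, yp, pv)
        yp[j] = y[j]
        for i in range(NSTATE):
            jac[i, j] = (fj[i] - f0[i]) / h
    return jac


#: observable vector layout returned by :func:`observables`
OBS_NAMES = ("P_LV", "P_RV", "P_SA", "P_SV", "P_PA", "P_PV",
             "Q_m", "Q_a", "Q_sa", "Q_t", "Q_p", "Q_pa",
             "sigma_XB_LV", "sigma_XB_SEP", "sigma_XB_RV",
             "Cm_SEP", "Ls_wall_LV", "Ls_wall_SEP", "Ls_wall_RV")


@njit(cache=True)
def observables(t, y, pv):
    """Pressures (mmHg), flows (mL/s), active stresses (kPa), septal curvature (1/cm)."""
    out = np.empty(len(OBS_NAMES))
    ls3 = y[33:36]
    g, ok = _solve_triseg(y[36:40].copy(), max(y[40], 1.0e-4), max(y[41], 1.0e-4),
                          ls3, pv, 1.0e-11, 30)
    p_lv, p_rv = _pressures_mmhg(g, ls3, pv)
    p_sa = (y[42] - pv[PV_VUN + 0]) / pv[PV_CSA]
    p_sv = (y[43] - pv[PV_VUN + 1]) / pv[PV_CSV]
    p_pa = (y[44] - pv[PV_VUN + 2]) / pv[PV_CPA]
    p_pv = (y[45] - pv[PV_VUN + 3]) / pv[PV_CPV]
    out[0], out[1], out[2], out[3], out[4], out[5] = p_lv, p_rv, p_sa, p_sv, p_pa, p_pv
    out[6] = _diode(p_pv - p_lv, pv[PV_RM])
    out[7] = _diode(p_lv - p_sa, pv[PV_RA]) * _avail(y[40])
    out[8] = (p_sa - p_sv) / pv[PV_RSA]
    out[9] = _diode(p_sv - p_rv, pv[PV_RT])
    out[10] = _diode(p_rv - p_pa, pv[PV_RP]) * _avail(y[41])
    out[11] = (p_pa - p_pv) / pv[PV_RPA]
    for iw in range(3):
        b = 11 * iw
        ov = _overlap(ls3[iw])
        out[12 + iw] = ov * (pv[PV_KSTIFF1 + iw] * (y[b + 4] + y[b + 7])
                             + pv[PV_KSTIFF2 + iw] * pv[PV_DR] * y[b + 6])
    xsep, ym = g[1], g[3]
    out[15] = 2.0 * xsep / (xsep * xsep + ym * ym)
    for iw in range(3):
        out[16 + iw] = _wall_ls_wall(iw, g, pv)
    return out
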