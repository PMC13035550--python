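"""Calcium activation, five-state crossbridge moment kinetics, and myofiber stresses.

The contractile machinery of one ventricular wall is described by a
five-state crossbridge scheme: three actin-myosin attached states
(A1 loosely bound, A2 strongly bound, A3 post-ratchet) and two unattached
states (U relaxed, U_SR super-relaxed), with occupancies summing to one.
Instead of tracking the full strain distribution of each attached state,
the model evolves its 0th-2nd statistical moments, closing the hierarchy at
second order, so each wall contributes eleven kinetic ODEs: nine moments,
the non-permissible thin-filament fraction ``N_np`` and the super-relaxed
fraction ``U_SR``.  A twelfth state, the contractile sarcomere length
``L_s``, evolves through a viscous force balance against a linear series
element.

Thin-filament regulation is a two-pseudo-state gate (permissible /
non-permissible) driven by cooperative Ca2+ binding to troponin C.  The
binding flux is ``k_on * Ca * (Ca / CA_GATE_REF)**(HILL_EXPONENT - 1)``;
the cooperativity exponent of 4 reflects measured cardiac force-pCa Hill
coefficients (typically 3-6) arising from regulatory-unit coupling along
the thin filament.

Metabolite coupling: cytosolic ATP, ADP and Pi modulate the transition
rates.  Pi rebinding drives the reverse A2 -> A1 flux and competes with Pi
release in A1; ADP rebinding and ATP binding gate the detachment of
post-ratchet crossbridges (A3 -> U).  See :func:`effective_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CalciumSchedule",
    "CrossbridgeParams",
    "EffectiveRates",
    "MyofiberParams",
    "WallMechState",
    "ForcePCaCurve",
    "calcium_transient",
    "effective_rates",
    "calcium_gate",
    "crossbridge_derivatives",
    "active_stress",
    "passive_stress",
    "viscous_stress",
    "myofiber_force_balance",
    "thick_filament_overlap",
    "simulate_force_pca",
    "steady_state_fractions",
    "pca_curve_summary",
    "parameter_direction_screen",
    "HILL_EXPONENT",
    "CA_GATE_REF",
    "PI_REF",
    "OVERLAP_KNOTS",
]

# --- structural constants (model form, not free parameters) ---------------

#: cooperativity of Ca2+ activation of the thin filament (dimensionless)
HILL_EXPONENT = 4.0
#: concentration scale making the cooperative gate dimensionally consistent (uM)
CA_GATE_REF = 1.0
#: reference Pi concentration for the second-order rebinding flux (uM)
PI_REF = 1000.0
#: thick/thin filament overlap tent: zero below, plateau edges, zero above (um)
OVERLAP_KNOTS = (1.60, 2.05, 2.30, 3.60)


class SarcomereError(ValueError):
    """Invalid sarcomere state, schedule or parameterization."""


@dataclass(frozen=True)
class CalciumSchedule:
    """Prescribed cytosolic Ca2+ transient for one cardiac cycle.

    The transient is a raised-cosine rise over ``T_S = k_TS * T`` followed
    by a raised-cosine fall over ``T_R = k_TR * T`` and a diastolic floor
    for the remainder of the cycle.
    """

    Ca_diastole: float = 0.1610  # uM, diastolic floor
    Ca_amplitude: float = 2.0    # uM, systolic amplitude
    k_TS: float = 0.08           # fraction of cycle spent rising
    k_TR: float = 0.40           # fraction of cycle spent falling
    T: float = 0.177             # cardiac period, s

    def __post_init__(self) -> None:
        for name in ("Ca_diastole", "Ca_amplitude", "k_TS", "k_TR", "T"):
            if getattr(self, name) <= 0.0:
                raise SarcomereError(f"{name} must be > 0")
        if self.k_TS + self.k_TR > 1.0 + 1e-12:
            raise SarcomereError("k_TS + k_TR must not exceed 1 "
                                 "(Ca transient must fit within one cycle)")

    @property
    def T_S(self) -> float:
        return self.k_TS * self.T

    @property
    def T_R(self) -> float:
        return self.k_TR * self.T


def calcium_transient(t, cs: CalciumSchedule):
    """Cytosolic Ca2+ concentration (uM) at time ``t`` within one cycle.

    Accepts a scalar or array ``t`` with ``0 <= t <= T``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > cs.T + 1e-12):
        raise SarcomereError("t outside [0, T]")
    ts, tr = cs.T_S, cs.T_R
    rise = cs.Ca_diastole + cs.Ca_amplitude * 0.5 * (1.0 - np.cos(np.pi * t_arr / ts))
    fall = cs.Ca_diastole + cs.Ca_amplitude * 0.5 * (
        1.0 + np.cos(np.pi * (t_arr - ts) / tr))
    out = np.where(t_arr < ts, rise, np.where(t_arr <= ts + tr, fall, cs.Ca_diastole))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class CrossbridgeParams:
    """Rate constants, stiffnesses and metabolite pools of one wall's crossbridge cycle.

    Rates in 1/s unless noted; concentrations in uM; stiffnesses in kPa/um.
    """

    k_a: float = 200.0      # actin-myosin attachment (already age-adjusted)
    k_d: float = 100.0      # A1 -> U detachment
    k_1: float = 150.0      # A1 -> A2 forward (Pi release)
    k_m1: float = 20.0      # A2 -> A1 reverse at the reference Pi
    k_3: float = 150.0      # A3 -> U detachment scale
    k_Pi: float = 1000.0    # Pi unbinding within A1
    k_ADP: float = 150.0    # A2 -> A3 ratchet (ADP-release limited)
    k_ATP: float = 400.0    # ATP-binding step of detachment
    k_SR: float = 15.0      # U -> U_SR (super-relaxed entry)
    k_mSR: float = 50.0     # U_SR -> U (super-relaxed exit)
    k_on: float = 100.0     # Ca2+ binding to troponin C, 1/(uM s)
    k_off: float = 520.0    # Ca2+ unbinding from troponin C
    K_D: float = 200.0      # ADP dissociation constant, uM
    K_T: float = 500.0      # ATP dissociation constant, uM
    k_stiff1: float = 1750.0   # strain-moment stiffness (myosin-actin), kPa/um
    k_stiff2: float = 20000.0  # working-stroke stiffness, kPa/um
    dr: float = 0.01        # ratchet displacement, um
    ATP: float = 8000.0     # cytosolic ATP, uM
    ADP: float = 50.0       # cytosolic ADP, uM
    Pi: float = 1000.0      # cytosolic inorganic phosphate, uM

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d", "k_1", "k_m1", "k_3", "k_Pi", "k_ADP",
                     "k_ATP", "k_SR", "k_mSR", "k_on", "k_off",
                     "k_stiff1", "k_stiff2", "dr"):
            if getattr(self, name) < 0.0:
                raise SarcomereError(f"{name} must be >= 0")
        for name in ("ATP", "ADP", "K_D", "K_T"):
            if getattr(self, name) <= 0.0:
                raise SarcomereError(f"{name} must be > 0")
        if self.Pi < 0.0:
            raise SarcomereError("Pi must be >= 0")


@dataclass(frozen=True)
class EffectiveRates:
    """Metabolite-modulated transition rates of the crossbridge cycle (1/s)."""

    k_a: float
    k_d: float
    k1_eff: float    # A1 -> A2, Pi-release pathway
    km1_eff: float   # A2 -> A1, second order in Pi (zero when Pi = 0)
    k_ADP: float     # A2 -> A3
    k3_eff: float    # A3 -> U, ATP-gated and ADP-inhibited
    k_SR: float
    k_mSR: float
    k_on: float
    k_off: float


def effective_rates(cb: CrossbridgeParams) -> EffectiveRates:
    """Fold the metabolite pools into the state-transition rates.

    * Pi rebinding: the reverse A2 -> A1 rate is ``k_m1 * Pi / PI_REF`` and
      competes with Pi unbinding (``k_Pi``) for the forward flux, so the
      rebinding contribution vanishes exactly at ``Pi = 0``.
    * Detachment: post-ratchet crossbridges release ADP (inhibited by ADP
      rebinding through ``K_D``) and must bind ATP (through ``K_T``) before
      detaching; the ATP-binding step saturates at ``k_ATP``.
    """
    if cb.ATP <= 0.0 or cb.ADP <= 0.0 or cb.Pi < 0.0:
        raise SarcomereError("metabolite concentrations must be positive (Pi >= 0)")
    pi_rebind = cb.k_m1 * cb.Pi / PI_REF
    k1_eff = cb.k_1 * cb.k_Pi / (cb.k_Pi + pi_rebind)
    phi = (cb.ATP / cb.K_T) / (1.0 + cb.ATP / cb.K_T + cb.ADP / cb.K_D)
    k3_atp = cb.k_3 * phi
    k3_eff = k3_atp * cb.k_ATP / (k3_atp + cb.k_ATP) if k3_atp > 0 else 0.0
    return EffectiveRates(
        k_a=cb.k_a, k_d=cb.k_d, k1_eff=k1_eff, km1_eff=pi_rebind,
        k_ADP=cb.k_ADP, k3_eff=k3_eff, k_SR=cb.k_SR, k_mSR=cb.k_mSR,
        k_on=cb.k_on, k_off=cb.k_off)


def calcium_gate(Ca: float, k_on: float) -> float:
    """Cooperative Ca2+ binding flux to troponin C (1/s)."""
    if Ca <= 0.0:
        return 0.0
    return k_on * Ca * (Ca / CA_GATE_REF) ** (HILL_EXPONENT - 1.0)


@dataclass(frozen=True)
class MyofiberParams:
    """Passive, viscous and series-elastic properties of one wall's myofibers."""

    k_passive: float = 1.3   # passive stiffness constant, kPa/um^gamma
    gamma: float = 2.0       # steepness of the length-tension relation
    L_sc0: float = 1.51      # contractile length at zero passive stress, um
    eta: float = 0.05        # viscosity, kPa s/um
    K_SE: float = 100.0      # series-element stiffness, kPa/um
    L_s_ref: float = 2.35    # sarcomere length at zero wall strain, um

    def __post_init__(self) -> None:
        if self.k_passive <= 0 or self.eta <= 0 or self.K_SE <= 0:
            raise SarcomereError("k_passive, eta, K_SE must be > 0")
        if self.gamma < 1.0:
            raise SarcomereError("gamma must be >= 1")
        if self.L_sc0 <= 0 or self.L_s_ref <= 0:
            raise SarcomereError("lengths must be > 0")


#: order of the eleven kinetic quantities in a wall state vector
KINETIC_FIELDS = ("p1_0", "p1_1", "p1_2", "p2_0", "p2_1", "p2_2",
                  "p3_0", "p3_1", "p3_2", "N_np", "U_SR")


@dataclass
class WallMechState:
    """Kinetic state of one wall: nine strain moments, regulatory and SR fractions, L_s.

    Moments ``p{i}_{n}`` are the n-th moments (0th unitless, 1st um,
    2nd um^2) of the attached-state strain distributions.  The unattached
    permissible pool is implied by conservation:
    ``U = 1 - p1_0 - p2_0 - p3_0 - U_SR``.
    """

    p1_0: float = 0.0
    p1_1: float = 0.0
    p1_2: float = 0.0
    p2_0: float = 0.0
    p2_1: float = 0.0
    p2_2: float = 0.0
    p3_0: float = 0.0
    p3_1: float = 0.0
    p3_2: float = 0.0
    N_np: float = 1.0
    U_SR: float = 0.0
    L_s: float = 2.0

    @property
    def U(self) -> float:
        return 1.0 - self.p1_0 - self.p2_0 - self.p3_0 - self.U_SR

    def validate(self) -> None:
        tol = 1e-9
        for name in ("p1_0", "p2_0", "p3_0", "N_np", "U_SR"):
            v = getattr(self, name)
            if not -tol <= v <= 1.0 + tol:
                raise SarcomereError(f"{name}={v} outside [0, 1]")
        if not -tol <= self.U <= 1.0 + tol:
            raise SarcomereError(f"unattached fraction U={self.U} outside [0, 1]")
        for name in ("p1_2", "p2_2", "p3_2"):
            if getattr(self, name) < -tol:
                raise SarcomereError(f"second moment {name} < 0")
        if self.L_s <= 0:
            raise SarcomereError("L_s must be > 0")

    def kinetic_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in KINETIC_FIELDS], dtype=float)

    @classmethod
    def from_kinetic_vector(cls, v, L_s: float) -> "WallMechState":
        kw = {f: float(x) for f, x in zip(KINETIC_FIELDS, v)}
        return cls(L_s=L_s, **kw)


def crossbridge_derivatives(w: WallMechState, Ca: float, overlap: float,
                            rates: EffectiveRates, dLs_dt: float = 0.0) -> np.ndarray:
    """Time derivatives of the eleven kinetic quantities (``L_s`` excluded).

    New attachments enter A1 at zero strain; strain moments advect with the
    half-sarcomere shortening velocity ``dLs_dt / 2``; all other transitions
    preserve strain.  Occupancy conservation is exact by construction.
    """
    if not 0.0 <= overlap <= 1.0:
        raise SarcomereError("overlap must be in [0, 1]")
    w.validate()
    (p10, p11, p12, p20, p21, p22, p30, p31, p32, Nnp, Usr) = w.kinetic_vector()
    U = 1.0 - p10 - p20 - p30 - Usr
    perm = 1.0 - Nnp
    v = 0.5 * dLs_dt
    att = rates.k_a * overlap * U * perm
    a1out = rates.k_d + rates.k1_eff
    a2out = rates.km1_eff + rates.k_ADP
    d = np.empty(11)
    d[0] = att - a1out * p10 + rates.km1_eff * p20
    d[1] = -a1out * p11 + rates.km1_eff * p21 + v * p10
    d[2] = -a1out * p12 + rates.km1_eff * p22 + 2.0 * v * p11
    d[3] = rates.k1_eff * p10 - a2out * p20
    d[4] = rates.k1_eff * p11 - a2out * p21 + v * p20
    d[5] = rates.k1_eff * p12 - a2out * p22 + 2.0 * v * p21
    d[6] = rates.k_ADP * p20 - rates.k3_eff * p30
    d[7] = rates.k_ADP * p21 - rates.k3_eff * p31 + v * p30
    d[8] = rates.k_ADP * p22 - rates.k3_eff * p32 + 2.0 * v * p31
    d[9] = rates.k_off * (1.0 - Nnp) - calcium_gate(Ca, rates.k_on) * Nnp
    d[10] = rates.k_SR * U - rates.k_mSR * Usr
    return d


def active_stress(w: WallMechState, overlap: float, cb: CrossbridgeParams) -> float:
    """Crossbridge active stress, kPa: strain moments of A2/A3 plus the ratchet term."""
    return overlap * (cb.k_stiff1 * (w.p2_1 + w.p3_1)
                      + cb.k_stiff2 * cb.dr * w.p3_0)


def passive_stress(L_s: float, mf: MyofiberParams) -> float:
    """Collagen-recruitment passive stress, kPa; zero below slack length."""
    if L_s <= 0:
        raise SarcomereError("L_s must be > 0")
    ext = L_s - mf.L_sc0
    if ext <= 0.0:
        return 0.0
    return mf.k_passive * ext ** mf.gamma


def viscous_stress(dLs_dt: float, eta: float) -> float:
    """Dashpot stress, kPa; sign follows the length rate."""
    return eta * dLs_dt


def myofiber_force_balance(L_s_wall: float, w: WallMechState, mf: MyofiberParams,
                           sigma_XB: float, sigma_pas: float):
    """Series-element stress and the induced sarcomere-length rate.

    The linear series element carries ``sigma_SE = K_SE * (L_s_wall - L_s)``;
    the viscous element absorbs the imbalance so the wall force balance
    sigma_SE = sigma_XB + sigma_pas + sigma_visc holds identically.

    Returns ``(dLs_dt, sigma_SE)``.
    """
    if mf.eta <= 0.0:
        raise SarcomereError("singular force balance: eta must be > 0")
    sigma_SE = mf.K_SE * (L_s_wall - w.L_s)
    dLs_dt = (sigma_SE - sigma_XB - sigma_pas) / mf.eta
    return dLs_dt, sigma_SE


def thick_filament_overlap(L_s: float) -> float:
    """Fraction of thick-filament overlap: piecewise-linear single-plateau tent."""
    if L_s <= 0:
        raise SarcomereError("L_s must be > 0")
    lo, p_lo, p_hi, hi = OVERLAP_KNOTS
    if L_s <= lo or L_s >= hi:
        return 0.0
    if L_s < p_lo:
        return (L_s - lo) / (p_lo - lo)
    if L_s <= p_hi:
        return 1.0
    return (hi - L_s) / (hi - p_hi)


# --- isolated force-pCa experiment ---------------------------------------

def steady_state_fractions(Ca: float, overlap: float, rates: EffectiveRates):
    """Closed-form steady occupancies (a1, a2, a3, U, U_SR, N_np) at fixed Ca.

    At steady state with no filament sliding the first and second strain
    moments vanish, so the occupancy balance is linear and solvable exactly.
    Serves as the fast path of the force-pCa solver and as an independent
    cross-check of the ODE integration.
    """
    gate = calcium_gate(Ca, rates.k_on)
    Nnp = rates.k_off / (rates.k_off + gate) if (rates.k_off + gate) > 0 else 1.0
    perm = 1.0 - Nnp
    a1out = rates.k_d + rates.k1_eff
    a2out = rates.km1_eff + rates.k_ADP
    # a_i = c_i * U
    denom = a1out - rates.km1_eff * rates.k1_eff / a2out
    c1 = rates.k_a * overlap * perm / denom
    c2 = rates.k1_eff * c1 / a2out
    c3 = rates.k_ADP * c2 / rates.k3_eff if rates.k3_eff > 0 else 0.0
    rho = rates.k_SR / rates.k_mSR if rates.k_mSR > 0 else 0.0
    U = 1.0 / (1.0 + rho + c1 + c2 + c3)
    return c1 * U, c2 * U, c3 * U, U, rho * U, Nnp


def _steady_force_at_ca(Ca: float, cb: CrossbridgeParams, sl: float) -> float:
    """Steady Ca2+-activated force at clamped sarcomere length ``sl``."""
    rates = effective_rates(cb)
    ov = thick_filament_overlap(sl)
    _, _, a3, _, _, _ = steady_state_fractions(Ca, ov, rates)
    return ov * cb.k_stiff2 * cb.dr * a3


def _integrated_force_at_ca(Ca, cb, sl, y0=None, t_max=10.0, steady_tol=1e-8):
    """Integrate the 11 kinetic states at fixed Ca and clamped ``L_s`` to steady state."""
    rates = effective_rates(cb)
    ov = thick_filament_overlap(sl)

    def rhs(t, y):
        w = WallMechState.from_kinetic_vector(y, sl)
        return crossbridge_derivatives(w, Ca, ov, rates, 0.0)

    if y0 is None:
        rho = rates.k_SR / rates.k_mSR
        y0 = np.zeros(11)
        y0[9] = 1.0
        y0[10] = rho / (1.0 + rho)
    scale = np.maximum(np.abs(y0), 1.0)

    def steady(t, y):
        return float(np.max(np.abs(rhs(t, y)) / scale) - steady_tol)
    steady.terminal = True
    steady.direction = -1

    sol = solve_ivp(rhs, (0.0, t_max), y0, method="BDF", rtol=1e-9, atol=1e-12,
                    events=steady, dense_output=False)
    if not sol.success:
        raise SarcomereError(f"force-pCa integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    if not sol.t_events[0].size and np.max(np.abs(rhs(sol.t[-1], y_end)) / scale) > steady_tol:
        raise SarcomereError(
            f"no steady state within {t_max} s at Ca={Ca} uM "
            f"(max scaled derivative {np.max(np.abs(rhs(sol.t[-1], y_end)) / scale):.3e})")
    w_end = WallMechState.from_kinetic_vector(y_end, sl)
    return active_stress(w_end, ov, cb), y_end


@dataclass
class ForcePCaCurve:
    """Steady-state force-pCa relation of the isolated, isometric myofiber."""

    pca: np.ndarray
    force_kpa: np.ndarray
    sl: float
    method: str = "steady"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"pCa": self.pca, "force_kPa": self.force_kpa})


def simulate_force_pca(cb: CrossbridgeParams, mf: MyofiberParams | None = None,
                       sl: float = 2.2, pca_grid=None,
                       method: str = "steady") -> ForcePCaCurve:
    """Simulate the skinned-fiber force-pCa experiment at fixed sarcomere length.

    For each grid point the Ca2+ concentration is clamped, the crossbridge
    system relaxes to steady state with the contractile sarcomere length
    held at ``sl`` (isometric), and the steady Ca2+-activated (crossbridge)
    force is recorded.  ``method='steady'`` solves the linear occupancy
    balance directly (exact at this model's closure); ``method='integrate'``
    integrates the kinetic ODEs until all scaled derivatives fall below 1e-8.
    ``mf`` is accepted for interface symmetry; the clamped protocol does not
    engage the passive or series elements.
    """
    if pca_grid is None:
        pca_grid = np.linspace(4.5, 7.0, 26)
    pca_grid = np.asarray(pca_grid, dtype=float)
    if np.any(np.diff(pca_grid) <= 0):
        raise SarcomereError("pCa grid must be strictly increasing (descending Ca)")
    forces = np.empty_like(pca_grid)
    y_prev = None
    for i, pca in enumerate(pca_grid):
        ca = 10.0 ** (-pca) * 1e6  # molar -> uM
        if method == "steady":
            forces[i] = _steady_force_at_ca(ca, cb, sl)
        elif method == "integrate":
            forces[i], y_prev = _integrated_force_at_ca(ca, cb, sl, y0=y_prev)
        else:
            raise ValueError(f"unknown method {method!r}")
    return ForcePCaCurve(pca=pca_grid, force_kpa=forces, sl=sl, method=method)


def pca_curve_summary(curve: ForcePCaCurve):
    """``(pCa50, Fmax)``: half-max crossing by linear interpolation, force at pCa 4.5."""
    pca, f = curve.pca, curve.force_kpa
    fmax = float(f[np.argmin(pca)])
    half = 0.5 * fmax
    below = f < half
    if not below.any() or below.all():
        raise SarcomereError("half-maximal force not bracketed by the pCa grid")
    i = int(np.argmax(below))  # first grid point below half-max (ascending pCa)
    if i == 0:
        raise SarcomereError("half-maximal force not bracketed by the pCa grid")
    f0, f1 = f[i - 1], f[i]
    p0, p1 = pca[i - 1], pca[i]
    pca50 = p0 + (half - f0) * (p1 - p0) / (f1 - f0)
    return float(pca50), fmax


#: Table of direction-screen perturbations: parameter -> (large_change?).
#: Large changes use x10 / /10; ordinary ones +/-20 %.
_SCREEN_PARAMS = {
    "k_stiff2": False, "dr": False, "k_1": True,
    "k_on": False, "k_off": False, "k_a": False,
    "k_3": False, "K_D": True, "K_T": True, "ATP": True, "ADP": True,
}


def parameter_direction_screen(param: str, direction: str,
                               cb: CrossbridgeParams | None = None,
                               mf: MyofiberParams | None = None,
                               sl: float = 2.2):
    """Signs of (dFmax, dpCa50) when one crossbridge parameter is perturbed.

    ``direction`` is ``'up'`` or ``'down'``; parameters flagged as requiring
    order-of-magnitude changes are scaled x10 (or /10), the rest by +/-20 %.
    Returns integers in {-1, 0, +1} for each effect.
    """
    if param not in _SCREEN_PARAMS:
        raise SarcomereError(f"unknown screen parameter {param!r}")
    if direction not in ("up", "down"):
        raise SarcomereError("direction must be 'up' or 'down'")
    cb = cb or CrossbridgeParams()
    mf = mf or MyofiberParams()
    big = _SCREEN_PARAMS[param]
    factor = (10.0 if big else 1.2) if direction == "up" else (0.1 if big else 1.0 / 1.2)
    cb_pert = replace(cb, **{param: getattr(cb, param) * factor})
    base = pca_curve_summary(simulate_force_pca(cb, mf, sl=sl))
    pert = pca_curve_summary(simulate_force_pca(cb_pert, mf, sl=sl))
    d_pca50 = pert[0] - base[0]
    d_fmax = pert[1] - base[1]
    tol_f = 1e-6 * max(base[1], 1e-12)
    tol_p = 1e-6
    sign = lambda x, tol: 0 if abs(x) < tol else (1 if x > 0 else -1)
    return sign(d_fmax, tol_f), sign(d_pca50, tol_p)
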