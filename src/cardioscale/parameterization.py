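"""Per-animal nominal parameterization and the hyperoxia modifiers.

The model has 54 free parameters, partitioned into sarcomere (crossbridge +
myofiber, with the four hyperoxia-remodelled entries resolved per wall),
TriSeg geometry, and circulation blocks.  Auxiliary per-animal quantities
that are fixed by data rather than free (cardiac period ``T``, total blood
volume ``V_total = 0.06 mL/g * BW``, and the zero-pressure volumes chosen
so nominal vascular pressures are met) ride along with the set but are not
counted in the registry.

Nominal rules:

* total blood volume 0.06 mL per gram of bodyweight;
* wall weights from condition-specific wall-weight-to-bodyweight ratios
  (mg/g), the LV taking 2/3 and the septum 1/3 of the LV+SEP weight, and a
  myocardial density of 1.055 g/mL;
* midwall reference areas from measured end-diastolic volumes assuming
  spherical geometry at the midwall radius;
* the actin-myosin attachment rate reduced 20 % from the adult value for
  all animals (pediatric age adjustment).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _core
from .sarcomere import CalciumSchedule, CrossbridgeParams, MyofiberParams, effective_rates

__all__ = [
    "AnimalRecord",
    "WallWeightRatios",
    "ParameterSet",
    "ParameterizationError",
    "nominal_parameters",
    "apply_hyperoxia_modifiers",
    "PARAMETER_NAMES",
    "WALLS",
    "ADULT_K_A",
    "PEDIATRIC_KA_FACTOR",
    "WALL_DENSITY_G_PER_ML",
    "BLOOD_ML_PER_G",
]

WALLS = ("LV", "SEP", "RV")

#: adult actin-myosin attachment rate, 1/s
ADULT_K_A = 250.0
#: pediatric (P21) reduction of the attachment rate
PEDIATRIC_KA_FACTOR = 0.8
#: myocardial density, g/mL
WALL_DENSITY_G_PER_ML = 1.055
#: total blood volume per bodyweight, mL/g
BLOOD_ML_PER_G = 0.06

#: effective spherical-shell area shares of the three walls: fixed
#: junction-depth corrections calibrated once against a uniform-stress
#: TriSeg solve at the control group-average end-diastolic geometry, placing
#: the end-diastolic sarcomere length at ~2.2 um (upper overlap plateau, the
#: stable limb of the length-tension relation).  The RV free wall wraps
#: beyond its hemisphere, hence a share above one.
AREA_SHARE = {"LV": 0.876, "SEP": 0.506, "RV": 1.489}

_WALL_SPECIFIC = ("k_passive", "k_off", "k_stiff1", "k_stiff2")
_SHARED_XB = ("k_a", "k_d", "k_1", "k_m1", "k_3", "k_Pi", "k_ADP", "k_ATP",
              "k_SR", "k_mSR", "k_on", "K_D", "K_T", "dr")
_METABOLITES = ("ATP", "ADP", "Pi")
_SHARED_MF = ("gamma", "L_sc0", "eta", "K_SE", "L_s_ref")
_CALCIUM = ("Ca_diastole", "Ca_amplitude", "k_TS", "k_TR")
_TRISEG = tuple(f"A_m_ref_{w}" for w in WALLS) + tuple(f"V_w_{w}" for w in WALLS)
_CIRC = ("C_SA", "C_SV", "C_PA", "C_PV", "R_SA", "R_PA", "R_m", "R_a", "R_t", "R_p")

PARAMETER_NAMES = (
    tuple(f"{p}_{w}" for p in _WALL_SPECIFIC for w in WALLS)
    + _SHARED_XB + _METABOLITES + _SHARED_MF + _CALCIUM + _TRISEG + _CIRC
)
assert len(PARAMETER_NAMES) == 54

SCHEMA_VERSION = 1


class ParameterizationError(ValueError):
    pass


@dataclass
class AnimalRecord:
    """One animal's measured static hemodynamics (units: g, s, uL, mmHg)."""

    id: str
    condition: str  # "Nx" or "Hx"
    sex: str        # "F" or "M"
    BW: float
    T: float
    SV: float
    ESV_LV: float
    ESV_RV: float
    EDP_LV: float
    EDP_RV: float
    ESP_LV: float
    ESP_RV: float
    waveforms: Optional[dict] = None  # optional beat-resolved traces

    def __post_init__(self):
        if self.condition not in ("Nx", "Hx"):
            raise ParameterizationError(f"condition must be Nx or Hx, got {self.condition}")
        if self.sex not in ("F", "M"):
            raise ParameterizationError(f"sex must be F or M, got {self.sex}")
        for name in ("BW", "T", "SV", "ESV_LV", "ESV_RV",
                     "EDP_LV", "EDP_RV", "ESP_LV", "ESP_RV"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ParameterizationError(f"missing or non-finite field {name}")
            if name not in ("EDP_LV", "EDP_RV") and v <= 0:
                raise ParameterizationError(f"{name} must be > 0")

    @property
    def EDV_LV(self) -> float:
        return self.ESV_LV + self.SV

    @property
    def EDV_RV(self) -> float:
        return self.ESV_RV + self.SV


@dataclass(frozen=True)
class WallWeightRatios:
    """Wall-weight-to-bodyweight ratios (mg/g) per condition.

    LV+SEP: Nx 3.8, Hx 3.2; RV: Nx 0.86, Hx 1.00; the LV takes 2/3 and the
    septum 1/3 of the combined LV+SEP weight.
    """

    nx_lvsep: float = 3.8
    nx_rv: float = 0.86
    hx_lvsep: float = 3.2
    hx_rv: float = 1.00

    def for_condition(self, condition: str):
        if condition == "Nx":
            return self.nx_lvsep, self.nx_rv
        if condition == "Hx":
            return self.hx_lvsep, self.hx_rv
        raise ParameterizationError(f"unknown condition {condition}")


@dataclass
class ParameterSet:
    """Named registry of the 54 model parameters plus per-animal auxiliaries."""

    values: dict
    T: float = 0.177            # cardiac period, s (data, not a free parameter)
    V_total: float = 3.0        # total blood volume, mL
    V_un: dict = field(default_factory=dict)  # zero-pressure volumes, mL
    condition: str = "Nx"
    animal_id: str = ""
    hx_applied: bool = False

    def __post_init__(self):
        missing = [n for n in PARAMETER_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in PARAMETER_NAMES]
        if missing or extra:
            raise ParameterizationError(
                f"parameter registry mismatch: missing={missing} extra={extra}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __setitem__(self, name: str, v: float) -> None:
        if name not in PARAMETER_NAMES:
            raise ParameterizationError(f"unknown parameter {name}")
        self.values[name] = float(v)

    def copy(self) -> "ParameterSet":
        return ParameterSet(values=dict(self.values), T=self.T, V_total=self.V_total,
                            V_un=dict(self.V_un), condition=self.condition,
                            animal_id=self.animal_id, hx_applied=self.hx_applied)

    # --- views ------------------------------------------------------------

    def calcium_schedule(self) -> CalciumSchedule:
        v = self.values
        return CalciumSchedule(Ca_diastole=v["Ca_diastole"], Ca_amplitude=v["Ca_amplitude"],
                               k_TS=v["k_TS"], k_TR=v["k_TR"], T=self.T)

    def crossbridge_params(self, wall: str) -> CrossbridgeParams:
        v = self.values
        return CrossbridgeParams(
            k_a=v["k_a"], k_d=v["k_d"], k_1=v["k_1"], k_m1=v["k_m1"], k_3=v["k_3"],
            k_Pi=v["k_Pi"], k_ADP=v["k_ADP"], k_ATP=v["k_ATP"], k_SR=v["k_SR"],
            k_mSR=v["k_mSR"], k_on=v["k_on"], k_off=v[f"k_off_{wall}"],
            K_D=v["K_D"], K_T=v["K_T"], k_stiff1=v[f"k_stiff1_{wall}"],
            k_stiff2=v[f"k_stiff2_{wall}"], dr=v["dr"],
            ATP=v["ATP"], ADP=v["ADP"], Pi=v["Pi"])

    def myofiber_params(self, wall: str) -> MyofiberParams:
        v = self.values
        return MyofiberParams(k_passive=v[f"k_passive_{wall}"], gamma=v["gamma"],
                              L_sc0=v["L_sc0"], eta=v["eta"], K_SE=v["K_SE"],
                              L_s_ref=v["L_s_ref"])

    # --- packing for the compiled core -------------------------------------

    def core_vector(self) -> np.ndarray:
        v = self.values
        er = effective_rates(self.crossbridge_params("LV"))  # shared rates
        pv = np.zeros(_core.PV_LEN)
        pv[_core.PV_KA] = v["k_a"]
        pv[_core.PV_KD] = v["k_d"]
        pv[_core.PV_K1E] = er.k1_eff
        pv[_core.PV_KM1E] = er.km1_eff
        pv[_core.PV_KADP] = v["k_ADP"]
        pv[_core.PV_K3E] = er.k3_eff
        pv[_core.PV_KSR] = v["k_SR"]
        pv[_core.PV_KMSR] = v["k_mSR"]
        pv[_core.PV_KON] = v["k_on"]
        pv[_core.PV_DR] = v["dr"]
        for i, w in enumerate(WALLS):
            pv[_core.PV_KOFF + i] = v[f"k_off_{w}"]
            pv[_core.PV_KSTIFF1 + i] = v[f"k_stiff1_{w}"]
            pv[_core.PV_KSTIFF2 + i] = v[f"k_stiff2_{w}"]
            pv[_core.PV_KPASSIVE + i] = v[f"k_passive_{w}"]
            pv[_core.PV_AMREF + i] = v[f"A_m_ref_{w}"]
            pv[_core.PV_VW + i] = v[f"V_w_{w}"]
        pv[_core.PV_GAMMA] = v["gamma"]
        pv[_core.PV_LSC0] = v["L_sc0"]
        pv[_core.PV_ETA] = v["eta"]
        pv[_core.PV_KSE] = v["K_SE"]
        pv[_core.PV_LSREF] = v["L_s_ref"]
        pv[_core.PV_CADIA] = v["Ca_diastole"]
        pv[_core.PV_CAAMP] = v["Ca_amplitude"]
        pv[_core.PV_TS] = v["k_TS"]
        pv[_core.PV_TR] = v["k_TR"]
        pv[_core.PV_T] = self.T
        pv[_core.PV_CSA] = v["C_SA"]
        pv[_core.PV_CSV] = v["C_SV"]
        pv[_core.PV_CPA] = v["C_PA"]
        pv[_core.PV_CPV] = v["C_PV"]
        pv[_core.PV_RSA] = v["R_SA"]
        pv[_core.PV_RPA] = v["R_PA"]
        pv[_core.PV_RM] = v["R_m"]
        pv[_core.PV_RA] = v["R_a"]
        pv[_core.PV_RT] = v["R_t"]
        pv[_core.PV_RP] = v["R_p"]
        for i, k in enumerate(("SA", "SV", "PA", "PV")):
            pv[_core.PV_VUN + i] = self.V_un[k]
        return pv

    # --- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "values": self.values,
            "T": self.T,
            "V_total": self.V_total,
            "V_un": self.V_un,
            "condition": self.condition,
            "animal_id": self.animal_id,
            "hx_applied": self.hx_applied,
        }
        s = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "ParameterSet":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            payload = json.loads(src)
        else:
            with open(src) as fh:
                payload = json.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ParameterizationError("unsupported parameter-set schema version")
        return cls(values=payload["values"], T=payload["T"], V_total=payload["V_total"],
                   V_un=payload["V_un"], condition=payload["condition"],
                   animal_id=payload.get("animal_id", ""),
                   hx_applied=payload.get("hx_applied", False))


# --- nominal construction --------------------------------------------------

#: parameters shared by every animal (the cell-scale and vascular baseline)
BASE_VALUES = {
    # shared crossbridge kinetics
    "k_a": ADULT_K_A * PEDIATRIC_KA_FACTOR,
    "k_d": 100.0, "k_1": 150.0, "k_m1": 20.0, "k_3": 150.0, "k_Pi": 1000.0,
    "k_ADP": 150.0, "k_ATP": 400.0, "k_SR": 15.0, "k_mSR": 50.0,
    "k_on": 100.0, "K_D": 200.0, "K_T": 500.0, "dr": 0.01,
    # metabolite pools (uM)
    "ATP": 8000.0, "ADP": 50.0, "Pi": 1000.0,
    # myofiber
    "gamma": 2.0, "L_sc0": 1.51, "eta": 0.05, "K_SE": 100.0, "L_s_ref": 2.35,
    # calcium transient
    "Ca_diastole": 0.1610, "Ca_amplitude": 2.0, "k_TS": 0.09, "k_TR": 0.35,
    # vascular compliances (mL/mmHg)
    "C_SA": 0.0012, "C_SV": 0.30, "C_PA": 0.0036, "C_PV": 0.04,
    # valve resistances (mmHg s/mL)
    "R_m": 0.5, "R_a": 1.2, "R_t": 0.8, "R_p": 1.0,
}
#: wall-specific baselines (before any hyperoxia remodelling); the thin RV
#: free wall is passively stiffer per unit thickness, pinning its
#: end-diastolic volume at the venous filling pressure
BASE_WALL_VALUES = {
    "k_passive": {"LV": 1.3, "SEP": 1.3, "RV": 5.0},
    "k_off": {"LV": 520.0, "SEP": 520.0, "RV": 520.0},
    "k_stiff1": {"LV": 1750.0, "SEP": 1750.0, "RV": 1750.0},
    "k_stiff2": {"LV": 20000.0, "SEP": 20000.0, "RV": 20000.0},
}

#: nominal mean vascular pressures used to place the zero-pressure volumes (mmHg)
NOMINAL_P = {"SV": 2.5, "PV": 9.5}
#: fraction of the end-systolic pressure taken as the mean arterial pressure
MEAN_OVER_ESP = 0.9
#: resting vascular volume fractions (of the non-ventricular blood volume)
VASC_FRACTION = {"SA": 0.15, "SV": 0.66, "PA": 0.05, "PV": 0.14}


def _sphere_radii(v_cavity_ml: float, v_wall_ml: float):
    """(cavity, outer, midwall) radii in cm of a thick spherical shell."""
    r_in = (3.0 * v_cavity_ml / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_out = (r_in ** 3 + 3.0 * v_wall_ml / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_in, r_out, 0.5 * (r_in + r_out)


def midwall_reference_area(v_cavity_ml: float, v_wall_ml: float, share: float) -> float:
    """Reference midwall area (cm^2): share of the sphere at the midwall radius."""
    _, _, r_m = _sphere_radii(v_cavity_ml, v_wall_ml)
    return share * 4.0 * math.pi * r_m ** 2


def cavity_volume_from_area(a_m_ref: float, v_wall_ml: float, share: float) -> float:
    """Invert :func:`midwall_reference_area`: cavity volume (mL) from the area."""
    from scipy.optimize import brentq
    r_m = math.sqrt(a_m_ref / (share * 4.0 * math.pi))

    def f(v):
        return _sphere_radii(v, v_wall_ml)[2] - r_m

    return brentq(f, 1e-9, 10.0, xtol=1e-14)


def nominal_parameters(rec: AnimalRecord,
                       wr: WallWeightRatios | None = None) -> ParameterSet:
    """Build the animal's nominal 54-parameter set from its record."""
    wr = wr or WallWeightRatios()
    wr_lvsep, wr_rv = wr.for_condition(rec.condition)

    v_total = BLOOD_ML_PER_G * rec.BW
    w_lvsep_g = wr_lvsep * rec.BW * 1e-3   # mg/g * g -> mg -> g
    w_rv_g = wr_rv * rec.BW * 1e-3
    v_w_lvsep = w_lvsep_g / WALL_DENSITY_G_PER_ML
    vw = {"LV": (2.0 / 3.0) * v_w_lvsep, "SEP": (1.0 / 3.0) * v_w_lvsep,
          "RV": w_rv_g / WALL_DENSITY_G_PER_ML}

    edv_lv_ml = rec.EDV_LV * 1e-3
    edv_rv_ml = rec.EDV_RV * 1e-3
    am = {
        "LV": midwall_reference_area(edv_lv_ml, vw["LV"] + vw["SEP"], AREA_SHARE["LV"]),
        "SEP": midwall_reference_area(edv_lv_ml, vw["LV"] + vw["SEP"], AREA_SHARE["SEP"]),
        "RV": midwall_reference_area(edv_rv_ml, vw["RV"], AREA_SHARE["RV"]),
    }

    co = rec.SV * 1e-3 / rec.T  # mL/s
    p_sa_mean = MEAN_OVER_ESP * rec.ESP_LV
    p_pa_mean = MEAN_OVER_ESP * rec.ESP_RV
    # venous working pressures track the measured filling pressures,
    # offset from the control-group anchors (Nx group means 2.9 / 4.4 mmHg)
    p_sv = NOMINAL_P["SV"] + (rec.EDP_RV - 2.9)
    p_pv = NOMINAL_P["PV"] + (rec.EDP_LV - 4.4)
    r_sa = (p_sa_mean - p_sv) / co
    r_pa = (p_pa_mean - p_pv) / co
    if r_sa <= 0 or r_pa <= 0:
        raise ParameterizationError("implausible record: nonpositive nominal resistance")

    values = dict(BASE_VALUES)
    for p, per_wall in BASE_WALL_VALUES.items():
        for w in WALLS:
            values[f"{p}_{w}"] = per_wall[w]
    for w in WALLS:
        values[f"A_m_ref_{w}"] = am[w]
        values[f"V_w_{w}"] = vw[w]
    values["R_SA"] = r_sa
    values["R_PA"] = r_pa

    # zero-pressure volumes placed so the resting allocation meets nominal pressures
    v_vasc = v_total - edv_lv_ml - edv_rv_ml
    if v_vasc <= 0:
        raise ParameterizationError("ventricular volumes exceed total blood volume")
    p_nom = {"SA": p_sa_mean, "SV": p_sv, "PA": p_pa_mean, "PV": p_pv}
    c_of = {"SA": values["C_SA"], "SV": values["C_SV"],
            "PA": values["C_PA"], "PV": values["C_PV"]}
    # floored at a small positive share so small animals stay admissible
    # (their compartment then simply runs at a slightly higher pressure)
    v_un = {k: max(VASC_FRACTION[k] * v_vasc - c_of[k] * p_nom[k], 0.005 * v_vasc)
            for k in VASC_FRACTION}

    return ParameterSet(values=values, T=rec.T, V_total=v_total, V_un=v_un,
                        condition=rec.condition, animal_id=rec.id, hx_applied=False)


#: multiplicative hyperoxia modifiers (RV-only for wall-specific entries)
HX_MODIFIERS = {"ATP": 0.95, "ADP": 1.05,
                "k_passive_RV": 2.0, "k_off_RV": 0.6,
                "k_stiff1_RV": 1.7, "k_stiff2_RV": 1.7}


def apply_hyperoxia_modifiers(p: ParameterSet, pi_sign: str = "text") -> ParameterSet:
    """Return a copy with the hyperoxia-induced parameter changes applied.

    ``pi_sign='text'`` increases Pi by 5 % (mitochondrial dysfunction raises
    ADP and Pi as ATP falls); ``pi_sign='table'`` decreases it by 5 %
    instead.  Both conventions appear in the source literature, so the
    choice is exposed rather than resolved.
    """
    if p.hx_applied:
        raise ParameterizationError("hyperoxia modifiers already applied")
    if pi_sign not in ("text", "table"):
        raise ParameterizationError("pi_sign must be 'text' or 'table'")
    out = p.copy()
    for name, factor in HX_MODIFIERS.items():
        out[name] = out[name] * factor
    out["Pi"] = out["Pi"] * (1.05 if pi_sign == "text" else 0.95)
    out.hx_applied = True
    out.condition = "Hx"
    return out
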