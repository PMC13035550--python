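"""Derived physiologic metrics, group statistics, and LDA separability.

Metrics extracted from a steady-state cycle: mean pulmonary arterial
pressure; septal-bounce depth (maximal systolic drop of septal midwall
curvature from its cycle-start value) and mean systolic septal curvature;
maximal absolute myofiber power intensity per wall; cycle-mean RV
sarcomere length; relative sarcomere shortening; ventricular stroke work
(PV-loop area); and the pulmonary afterload triplet (R/C ratio, RC time).

Unit notes: stroke work in uL*mmHg; power intensity converts
kPa*um/s -> W/m^2 via the factor 1e-3; pulmonary arterial compliance is
reported both in mL/mmHg and cm^3/kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .heart import CycleSeries
from .units import CM3_PER_KPA_PER_ML_PER_MMHG, W_PER_M2_PER_KPA_UM_S

__all__ = ["MetricsRecord", "MetricsError", "cycle_endpoints", "relative_shortening",
           "power_intensity", "septal_metrics", "stroke_work", "afterload_metrics",
           "systole_window", "compute_metrics", "group_comparisons",
           "lda_separability", "LDAResult"]


class MetricsError(ValueError):
    pass


def cycle_endpoints(c: CycleSeries) -> dict:
    """EDV/ESV at the volume extremes and the pressures at those instants."""
    return c.octet


def relative_shortening(ls_trace: np.ndarray) -> np.ndarray:
    """(L_s(t) - L_s(0)) / L_s(0); unitless, exactly zero at the cycle start."""
    ls = np.asarray(ls_trace, dtype=float)
    if ls[0] <= 0:
        raise MetricsError("L_s(0) must be > 0")
    return (ls - ls[0]) / ls[0]


def power_intensity(sigma_xb: np.ndarray, ls: np.ndarray, t: np.ndarray) -> float:
    """Max |myofiber power intensity| over the cycle, W/m^2.

    Work intensity accumulates as the discrete integral of active stress
    over sarcomere length; power is its discrete time derivative.
    """
    sigma = np.asarray(sigma_xb, dtype=float)
    ls = np.asarray(ls, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (len(sigma) == len(ls) == len(t)):
        raise MetricsError("traces must be aligned")
    d_ls = np.diff(ls)
    work = np.concatenate([[0.0], np.cumsum(0.5 * (sigma[1:] + sigma[:-1]) * d_ls)])
    power = np.gradient(work, t)  # kPa um / s
    return float(np.max(np.abs(power)) * W_PER_M2_PER_KPA_UM_S)


def systole_window(c: CycleSeries, vent: str = "RV") -> np.ndarray:
    """Boolean mask from inflow-valve closure to outflow-valve closure.

    Valve events come from the simulated flows: systole starts when the
    inflow (mitral/tricuspid) flow shuts and ends when the outflow
    (aortic/pulmonary) flow shuts after ejection.
    """
    q_in = c.flows["Q_m"] if vent == "LV" else c.flows["Q_t"]
    q_out = c.flows["Q_a"] if vent == "LV" else c.flows["Q_p"]
    n = len(q_in)
    tol_in = 1e-3 * max(q_in.max(), 1e-9)
    tol_out = 1e-3 * max(q_out.max(), 1e-9)
    open_in = q_in > tol_in
    # first index where inflow has just closed
    closes = [i for i in range(n) if open_in[i - 1] and not open_in[i]]
    start = closes[0] if closes else 0
    ej = np.where(q_out > tol_out)[0]
    if ej.size == 0:
        end = start
    else:
        # last ejection index at/after start (cyclically)
        rel = (ej - start) % n
        end = int(ej[np.argmax(rel)])
    idx = (np.arange(n) - start) % n
    span = (end - start) % n
    return idx <= span


def septal_metrics(cm_sep: np.ndarray, window: np.ndarray):
    """(septal bounce, mean systolic curvature), both 1/cm.

    Bounce is the maximal drop of septal curvature during systole from the
    value at the start of the cycle; drops outside the window are ignored.
    """
    cm = np.asarray(cm_sep, dtype=float)
    w = np.asarray(window, dtype=bool)
    if cm.shape != w.shape:
        raise MetricsError("window must align with the curvature trace")
    if not w.any():
        return 0.0, float("nan")
    drop = float(cm[0] - cm[w].min())
    return max(drop, 0.0), float(cm[w].mean())


def stroke_work(p: np.ndarray, v: np.ndarray) -> float:
    """Signed PV-loop area by the shoelace rule, uL*mmHg; positive counterclockwise.

    The counterclockwise convention corresponds to the physiological loop
    traversal in the (V, P) plane (ejection at high pressure, filling low).
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def afterload_metrics(r_pa: float, c_pa: float, p_pa: np.ndarray):
    """(mPAP mmHg, R/C ratio, RC time s) for the pulmonary circulation."""
    if r_pa <= 0 or c_pa <= 0:
        raise MetricsError("R_PA and C_PA must be positive")
    mpap = float(np.mean(p_pa))
    return mpap, r_pa / c_pa, r_pa * c_pa


@dataclass
class MetricsRecord:
    """Derived metrics for one calibrated animal."""

    animal_id: str
    condition: str
    mPAP: float
    dCm_SEP: float
    mean_systolic_Cm_SEP: float
    power_intensity: dict            # wall -> W/m^2
    mean_Ls_RV: float
    SW_LV: float
    SW_RV: float
    C_PA_ml_mmHg: float
    C_PA_cm3_kpa: float
    R_over_C: float
    RC_time: float
    octet: dict = field(default_factory=dict)
    relative_shortening_RV: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {"animal": self.animal_id, "condition": self.condition,
             "mPAP": self.mPAP, "dCm_SEP": self.dCm_SEP,
             "mean_systolic_Cm_SEP": self.mean_systolic_Cm_SEP,
             "mean_Ls_RV": self.mean_Ls_RV, "SW_LV": self.SW_LV,
             "SW_RV": self.SW_RV, "C_PA_cm3_kpa": self.C_PA_cm3_kpa,
             "R_over_C": self.R_over_C, "RC_time": self.RC_time}
        d.update({f"power_{w}": v for w, v in self.power_intensity.items()})
        d.update(self.octet)
        return d


def compute_metrics(cycle: CycleSeries, params, animal_id: str = "",
                    condition: str = "") -> MetricsRecord:
    """All derived metrics from one steady-state cycle and its parameter set."""
    r_pa, c_pa = params["R_PA"], params["C_PA"]
    mpap, roc, rc = afterload_metrics(r_pa, c_pa, cycle.P_PA)
    win = systole_window(cycle, vent="RV")
    bounce, mean_sys = septal_metrics(cycle.Cm_SEP, win)
    power = {w: power_intensity(cycle.sigma_XB[w], cycle.L_s[w], cycle.t)
             for w in ("LV", "SEP", "RV")}
    return MetricsRecord(
        animal_id=animal_id or getattr(params, "animal_id", ""),
        condition=condition or getattr(params, "condition", ""),
        mPAP=mpap, dCm_SEP=bounce, mean_systolic_Cm_SEP=mean_sys,
        power_intensity=power,
        mean_Ls_RV=float(np.mean(cycle.L_s["RV"])),
        SW_LV=stroke_work(cycle.P_LV, cycle.V_LV),
        SW_RV=stroke_work(cycle.P_RV, cycle.V_RV),
        C_PA_ml_mmHg=c_pa,
        C_PA_cm3_kpa=c_pa * CM3_PER_KPA_PER_ML_PER_MMHG,
        R_over_C=roc, RC_time=rc,
        octet=cycle.octet,
        relative_shortening_RV=relative_shortening(cycle.L_s["RV"]))


# --- group statistics ------------------------------------------------------

def group_comparisons(df: pd.DataFrame, metrics=None, pearson_pairs=None,
                      spearman_pairs=None, by_sex: bool = False) -> dict:
    """Unpaired t-tests Nx vs Hx plus requested correlation tests.

    ``df`` carries one row per animal with a ``condition`` column (and
    optionally ``sex``).  Groups with fewer than two animals are skipped
    with a note rather than an error.
    """
    out = {"t_tests": [], "pearson": [], "spearman": [], "skipped": []}
    metrics = metrics or [c for c in df.columns
                          if c not in ("animal", "condition", "sex")
                          and np.issubdtype(df[c].dtype, np.number)]

    def _t(sub, label):
        nx = sub[sub.condition == "Nx"]
        hx = sub[sub.condition == "Hx"]
        for m in metrics:
            a, b = nx[m].dropna(), hx[m].dropna()
            if len(a) < 2 or len(b) < 2:
                out["skipped"].append({"metric": m, "stratum": label,
                                       "reason": "group size < 2"})
                continue
            t, p = sps.ttest_ind(a, b, equal_var=True)
            out["t_tests"].append({"metric": m, "stratum": label,
                                   "mean_Nx": float(a.mean()), "sd_Nx": float(a.std(ddof=1)),
                                   "mean_Hx": float(b.mean()), "sd_Hx": float(b.std(ddof=1)),
                                   "t": float(t), "p": float(p),
                                   "significant": bool(p < 0.05)})

    _t(df, "all")
    if by_sex and "sex" in df.columns:
        for sex in sorted(df.sex.unique()):
            _t(df[df.sex == sex], f"sex={sex}")

    for pairs, key, fn in ((pearson_pairs, "pearson", sps.pearsonr),
                           (spearman_pairs, "spearman", sps.spearmanr)):
        for a, b in (pairs or []):
            sub = df[[a, b]].dropna()
            if len(sub) < 3:
                out["skipped"].append({"metric": f"{a}~{b}", "stratum": key,
                                       "reason": "n < 3"})
                continue
            rho, p = fn(sub[a], sub[b])
            out[key].append({"x": a, "y": b, "rho": float(rho), "p": float(p),
                             "significant": bool(p < 0.05)})
    return out


# --- linear discriminant separability --------------------------------------

@dataclass
class LDAResult:
    """Fisher-discriminant projection of one feature set."""

    feature_set: str
    direction: np.ndarray
    projections: np.ndarray
    labels: np.ndarray
    separation: float           # between-class over within-class scatter
    shrinkage: float

    def group_stats(self) -> dict:
        out = {}
        for lab in np.unique(self.labels):
            z = self.projections[self.labels == lab]
            out[str(lab)] = {"mean": float(z.mean()),
                             "var": float(z.var(ddof=1)) if len(z) > 1 else 0.0}
        return out


def lda_separability(features: pd.DataFrame, labels, feature_set: str = "",
                     shrinkage: float = 0.1) -> LDAResult:
    """Fisher discriminant with shrinkage-regularized within-class scatter.

    Features are standardized to zero mean / unit variance; the
    within-class scatter is blended with its diagonal average
    (``(1 - a) Sw + a tr(Sw)/d I``) so small cohorts with many features
    remain solvable.  The separation index is the ratio of between-class
    to within-class scatter along the discriminant direction.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise MetricsError("LDA separability is defined for two classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    d = Z.shape[1]
    means = {c: Z[y == c].mean(axis=0) for c in classes}
    sw = np.zeros((d, d))
    for c in classes:
        zc = Z[y == c] - means[c]
        sw += zc.T @ zc
    sw /= max(len(y) - 2, 1)
    applied = shrinkage
    sw_reg = (1.0 - applied) * sw + applied * (np.trace(sw) / d) * np.eye(d)
    try:
        w = np.linalg.solve(sw_reg, means[classes[1]] - means[classes[0]])
    except np.linalg.LinAlgError:
        applied = max(shrinkage, 0.5)
        sw_reg = (1.0 - applied) * sw + applied * (np.trace(sw) / d) * np.eye(d)
        w = np.linalg.solve(sw_reg, means[classes[1]] - means[classes[0]])
    nw = np.linalg.norm(w)
    if nw == 0:
        w = np.ones(d) / np.sqrt(d)
    else:
        w = w / nw
    z = Z @ w
    z0, z1 = z[y == classes[0]], z[y == classes[1]]
    between = (z0.mean() - z1.mean()) ** 2
    within = (z0.var(ddof=1) if len(z0) > 1 else 0.0) + \
             (z1.var(ddof=1) if len(z1) > 1 else 0.0)
    sep = between / within if within > 0 else np.inf
    return LDAResult(feature_set=feature_set, direction=w, projections=z,
                     labels=y, separation=float(sep), shrinkage=applied)
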