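"""Conductance-catheter data corrections: raw beats to calibration-ready cycles.

The LV and RV are catheterized sequentially (not simultaneously), so the
two recordings disagree in cycle duration and stroke volume and carry
pressure-calibration and isovolumetric-phase artifacts.  The pipeline is
order-stable:

    average -> harmonize timing/volumes -> EDP-correct -> enforce
    isovolumic phases -> resample to the common N = 50 grid

Conventions: end-diastole at maximum volume, end-systole at minimum volume
of the averaged cycle; the resampling grid is uniform and half-open
[0, T).  The common stroke volume is the LV's (the conductance measurement
is more accurate for LV geometry), and the RV end-diastolic volume is reset
to ``RV ESV + SV``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["BeatSeries", "PreparedData", "DataPrepError",
           "average_beats", "harmonize_timing_volumes", "correct_edp_offset",
           "enforce_isovolumic", "prepare_animal", "N_GRID"]

#: common resampling grid length per cycle
N_GRID = 50


class DataPrepError(ValueError):
    pass


@dataclass
class BeatSeries:
    """Beat-segmented pressure/volume recording for one ventricle.

    ``beats`` is a list of (t, P, V) arrays, one per beat, each starting at
    its own beat onset (t[0] = 0); pressures mmHg, volumes uL, time s.
    """

    ventricle: str                 # "LV" or "RV"
    beats: list
    sampling_rate: float           # Hz

    def __post_init__(self):
        if self.ventricle not in ("LV", "RV"):
            raise DataPrepError("ventricle must be LV or RV")
        if any(len(b[0]) < 4 for b in self.beats):
            raise DataPrepError("degenerate beat with fewer than 4 samples")
        for t, _, _ in self.beats:
            if t[-1] <= 0:
                raise DataPrepError("beat duration must be positive")

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    @property
    def mean_period(self) -> float:
        """Mean beat duration; each beat spans [0, T) so T = t[-1] + dt."""
        durations = []
        for t, _, _ in self.beats:
            dt = (t[-1] - t[0]) / (len(t) - 1)
            durations.append(t[-1] + dt)
        return float(np.mean(durations))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ventricle: str,
                   sampling_rate: float) -> "BeatSeries":
        """Build from a long-format table with columns t_s, P_mmHg, V_uL, beat_id."""
        beats = []
        for _, grp in df.groupby("beat_id", sort=True):
            t = grp["t_s"].to_numpy(dtype=float)
            beats.append((t - t[0], grp["P_mmHg"].to_numpy(dtype=float),
                          grp["V_uL"].to_numpy(dtype=float)))
        return cls(ventricle=ventricle, beats=beats, sampling_rate=sampling_rate)


@dataclass
class AveragedCycle:
    """Phase-averaged single cycle on the common grid (internal intermediate)."""

    ventricle: str
    T: float
    P: np.ndarray
    V: np.ndarray

    @property
    def sv(self) -> float:
        return float(self.V.max() - self.V.min())


def average_beats(b: BeatSeries, n: int = N_GRID) -> AveragedCycle:
    """Time-normalize each beat to unit phase and average pointwise.

    Fewer than 20 beats triggers a warning (the protocol selects 20-50);
    zero beats is an error.
    """
    if b.n_beats == 0:
        raise DataPrepError("no beats to average")
    if b.n_beats < 20:
        warnings.warn(f"only {b.n_beats} beats available (protocol selects 20-50)",
                      stacklevel=2)
    phase = np.arange(n) / n
    acc_p = np.zeros(n)
    acc_v = np.zeros(n)
    for t, p, v in b.beats:
        ph = t / t[-1]
        acc_p += np.interp(phase, ph, p)
        acc_v += np.interp(phase, ph, v)
    return AveragedCycle(ventricle=b.ventricle, T=b.mean_period,
                         P=acc_p / b.n_beats, V=acc_v / b.n_beats)


def harmonize_timing_volumes(lv: AveragedCycle, rv: AveragedCycle):
    """Common period and stroke volume for the asynchronously recorded sides.

    Returns ``(T_common, SV_common, rv_adjusted)``: the common period is the
    mean of the two cycle durations; the common SV is the LV stroke volume;
    the RV volume trace is rescaled affinely so its extremes match
    ``RV ESV`` (kept) and ``RV EDV = RV ESV + SV_common``.
    """
    t_common = 0.5 * (lv.T + rv.T)
    sv_common = lv.sv
    rv_esv = float(rv.V.min())
    old_sv = rv.sv
    if old_sv <= 0:
        raise DataPrepError("degenerate RV volume trace")
    v_adj = rv_esv + (rv.V - rv_esv) * (sv_common / old_sv)
    rv_adjusted = AveragedCycle(ventricle="RV", T=t_common, P=rv.P.copy(), V=v_adj)
    return t_common, sv_common, rv_adjusted


def correct_edp_offset(cycle: AveragedCycle, group_reference_edp: float) -> AveragedCycle:
    """Shift the pressure trace upward when the measured EDP is negative.

    The end-diastolic pressure (at maximum volume) is matched to the group
    reference (same condition and sex, animals with nonnegative EDP); a
    constant shift preserves pulse pressure exactly.
    """
    if not np.isfinite(group_reference_edp):
        raise DataPrepError("no valid group reference EDP")
    edp = _plateau_edp(cycle.P, cycle.V)
    if edp >= 0.0:
        return cycle
    return AveragedCycle(ventricle=cycle.ventricle, T=cycle.T,
                         P=cycle.P + (group_reference_edp - edp), V=cycle.V.copy())


def _plateau_edp(p, v, plateau: float = 0.02) -> float:
    """EDP as the pressure minimum on the end-diastolic volume plateau."""
    v = np.asarray(v, dtype=float)
    sv = max(v.max() - v.min(), 1e-12)
    return float(np.asarray(p)[v >= v.max() - plateau * sv].min())


def enforce_isovolumic(cycle: AveragedCycle) -> AveragedCycle:
    """Pin the volume during isovolumetric contraction and relaxation.

    Catheter positioning produces non-physiological volume wiggles while
    both valves are closed.  With the cycle starting at end-diastole
    (maximum volume), the contraction phase runs from the EDV point until
    volume first leaves EDV for good (pressure rising), and relaxation
    around the ESV point; volume is clamped to EDV / ESV on those segments.
    Ejection and filling segments, and hence the stroke volume, are
    untouched.
    """
    v = cycle.V.copy()
    p = cycle.P
    n = len(v)
    i_ed = int(np.argmax(v))
    i_es = int(np.argmin(v))
    edv, esv = v[i_ed], v[i_es]
    if i_ed == i_es:
        raise DataPrepError("volume extrema not identifiable")
    sv = edv - esv
    # isovolumetric contraction: clamp to EDV while the pressure is still
    # below the ejection level and the volume has not genuinely dropped;
    # low-pressure dips near EDV are catheter artifacts, true ejection is
    # recognized by the pressure rise
    p_open = p[i_ed] + 0.25 * (p.max() - p[i_ed])
    for step in range(1, n):
        j = (i_ed + step) % n
        if v[j] < edv - 0.25 * sv or p[j] >= p_open:
            break
        v[j] = edv
    # isovolumetric relaxation: clamp to ESV until filling decisively
    # begins (a sustained volume rise clear of the ESV plateau)
    for step in range(1, n):
        j = (i_es + step) % n
        nxt = (j + 1) % n
        if v[j] > esv + 0.25 * sv:
            break
        if v[j] > esv + 0.02 * sv and v[nxt] >= v[j]:
            break
        v[j] = esv
    return AveragedCycle(ventricle=cycle.ventricle, T=cycle.T, P=p.copy(), V=v)


@dataclass
class PreparedData:
    """Calibration-ready averaged cycles and the static octet for one animal.

    ``P_LV/V_LV/P_RV/V_RV`` are on the common half-open N-point grid
    (mmHg / uL); the octet keys are EDV/ESV/EDP/ESP x LV/RV.
    """

    animal_id: str
    T: float
    SV: float
    P_LV: np.ndarray
    V_LV: np.ndarray
    P_RV: np.ndarray
    V_RV: np.ndarray
    octet: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.octet:
            self.octet = self._compute_octet()

    def _compute_octet(self) -> dict:
        from .heart import volume_extreme_octet
        return volume_extreme_octet(self.V_LV, self.P_LV, self.V_RV, self.P_RV)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.P_LV)) / len(self.P_LV) * self.T
        return pd.DataFrame({"t_s": t, "P_LV_mmHg": self.P_LV, "V_LV_uL": self.V_LV,
                             "P_RV_mmHg": self.P_RV, "V_RV_uL": self.V_RV})

    @classmethod
    def from_record(cls, rec) -> "PreparedData":
        """Static-only preparation from an AnimalRecord (no waveforms).

        Builds smooth synthetic-free placeholder traces implied by the
        octet for code paths that require a grid; the octet itself is
        exact.  Used when only Table-style static data are available.
        """
        n = N_GRID
        ph = np.arange(n) / n
        # plausible monotone segments between the octet corners (schematic)
        v_lv = _schematic_volume(rec.EDV_LV, rec.ESV_LV, ph)
        v_rv = _schematic_volume(rec.EDV_RV, rec.ESV_RV, ph)
        p_lv = _schematic_pressure(rec.EDP_LV, rec.ESP_LV, ph)
        p_rv = _schematic_pressure(rec.EDP_RV, rec.ESP_RV, ph)
        octet = {"EDV_LV": rec.EDV_LV, "ESV_LV": rec.ESV_LV,
                 "EDP_LV": rec.EDP_LV, "ESP_LV": rec.ESP_LV,
                 "EDV_RV": rec.EDV_RV, "ESV_RV": rec.ESV_RV,
                 "EDP_RV": rec.EDP_RV, "ESP_RV": rec.ESP_RV}
        return cls(animal_id=rec.id, T=rec.T, SV=rec.SV, P_LV=p_lv, V_LV=v_lv,
                   P_RV=p_rv, V_RV=v_rv, octet=octet)


def _schematic_volume(edv, esv, ph):
    """EDV plateau, cosine ejection, ESV plateau, cosine refill, EDV plateau.

    Built so the plateau-based octet read of the trace reproduces the
    record's volumes exactly.
    """
    v = np.full_like(ph, edv)
    ej = (ph >= 0.08) & (ph < 0.42)
    v[ej] = edv - (edv - esv) * 0.5 * (1 - np.cos(np.pi * (ph[ej] - 0.08) / 0.34))
    v[(ph >= 0.42) & (ph < 0.58)] = esv
    fill = (ph >= 0.58) & (ph < 0.98)
    v[fill] = esv + (edv - esv) * 0.5 * (1 - np.cos(np.pi * (ph[fill] - 0.58) / 0.40))
    return v


def _schematic_pressure(edp, esp, ph):
    """Pressure consistent with the octet: EDP at the ED plateau, ESP at ES.

    Isovolumetric rise over the ED plateau, slow rise to ESP through
    ejection, fall back toward EDP during relaxation and diastole.
    """
    p = np.full_like(ph, edp)
    rise = ph < 0.08
    p[rise] = edp + (0.92 * esp - edp) * (ph[rise] / 0.08)
    ej = (ph >= 0.08) & (ph < 0.42)
    p[ej] = esp * (0.92 + 0.08 * (ph[ej] - 0.08) / 0.34)
    fall = (ph >= 0.42) & (ph < 0.62)
    p[fall] = edp + (esp - edp) * 0.5 * (1 + np.cos(np.pi * (ph[fall] - 0.42) / 0.20))
    return p


def prepare_animal(lv_beats: BeatSeries, rv_beats: BeatSeries, animal_id: str,
                   group_reference_edp: Optional[dict] = None) -> PreparedData:
    """Full preprocessing pipeline for one animal's raw recordings."""
    lv = average_beats(lv_beats)
    rv = average_beats(rv_beats)
    t_common, sv_common, rv = harmonize_timing_volumes(lv, rv)
    lv = AveragedCycle("LV", t_common, lv.P, lv.V)
    if group_reference_edp is not None:
        lv = correct_edp_offset(lv, group_reference_edp.get("LV", np.nan))
        rv = correct_edp_offset(rv, group_reference_edp.get("RV", np.nan))
    else:
        for c in (lv, rv):
            if _plateau_edp(c.P, c.V) < 0:
                raise DataPrepError(
                    f"negative {c.ventricle} EDP and no group reference supplied")
    lv = enforce_isovolumic(lv)
    rv = enforce_isovolumic(rv)
    return PreparedData(animal_id=animal_id, T=t_common, SV=sv_common,
                        P_LV=lv.P, V_LV=lv.V, P_RV=rv.P, V_RV=rv.V)


def group_reference_edp(records, condition: str, sex: str) -> dict:
    """Mean measured EDP of same-condition-and-sex animals with nonnegative EDP."""
    out = {}
    for vent, attr in (("LV", "EDP_LV"), ("RV", "EDP_RV")):
        vals = [getattr(r, attr) for r in records
                if r.condition == condition and r.sex == sex and getattr(r, attr) >= 0]
        if not vals:
            raise DataPrepError(
                f"no valid reference animals for {condition}/{sex} {vent}")
        out[vent] = float(np.mean(vals))
    return out
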