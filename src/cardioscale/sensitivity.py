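"""Local log-scale sensitivity of pressure-volume outputs and FIM subset screening.

The sensitivity target is the concatenated steady-state LV/RV volume and
pressure traces on the common N-point grid (4N outputs).  Derivatives are
centered differences on log-parameters with half-width ``h = 0.01``, taken
over the 18 organ-scale and timing parameters:

    C_SA C_SV C_PA C_PV R_SA R_PA R_m R_a R_t R_p
    A_m_ref_RV A_m_ref_LV A_m_ref_SEP V_w_RV V_w_LV V_w_SEP k_TS k_TR

Per animal, each parameter's scalar sensitivity is the Euclidean norm of
its column, normalized to the animal's maximum so values span [0, 1];
parameters with normalized sensitivity above 0.1 count as influential.
Subsets are screened through the approximate Fisher information matrix
F = S^T S, accepted only when cond(F) < 1e8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heart import run_to_steady_state
from .parameterization import ParameterSet

__all__ = ["SENSITIVITY_PARAMETERS", "CALIBRATION_SUBSET", "SENSITIVITY_THRESHOLD",
           "FIM_CONDITION_LIMIT", "SensitivityMatrix", "RankingTable",
           "SensitivityError", "pv_output_vector", "local_sensitivity",
           "normalize_and_rank", "fim_condition", "select_parameter_subset"]

#: the 18 organ-scale + timing parameters screened for influence
SENSITIVITY_PARAMETERS = (
    "C_SA", "C_SV", "C_PA", "C_PV", "R_SA", "R_PA", "R_m", "R_a", "R_t", "R_p",
    "A_m_ref_RV", "A_m_ref_LV", "A_m_ref_SEP", "V_w_RV", "V_w_LV", "V_w_SEP",
    "k_TS", "k_TR")

#: the ten-parameter subset retained for calibration in both conditions
CALIBRATION_SUBSET = ("R_SA", "R_PA", "A_m_ref_LV", "A_m_ref_SEP", "A_m_ref_RV",
                      "V_w_LV", "V_w_SEP", "V_w_RV", "k_TS", "k_TR")

SENSITIVITY_THRESHOLD = 0.1
FIM_CONDITION_LIMIT = 1.0e8


class SensitivityError(RuntimeError):
    pass


def pv_output_vector(cycle) -> np.ndarray:
    """Concatenated [V_LV, V_RV, P_LV, P_RV] steady-cycle traces (length 4N)."""
    return np.concatenate([cycle.V_LV, cycle.V_RV, cycle.P_LV, cycle.P_RV])


@dataclass
class SensitivityMatrix:
    """Centered-difference log-scale sensitivities, 4N outputs x parameters."""

    S: np.ndarray
    parameters: tuple
    animal_id: str = ""
    h: float = 0.01

    def column(self, name: str) -> np.ndarray:
        return self.S[:, self.parameters.index(name)]


def _default_runner(params: ParameterSet, y0=None, **kw):
    kw.setdefault("tol", 1e-3)
    kw.setdefault("rtol", 1e-6)
    cycle = run_to_steady_state(params, y0=y0, **kw)
    return pv_output_vector(cycle), cycle.final_state


def local_sensitivity(params: ParameterSet, parameters=SENSITIVITY_PARAMETERS,
                      h: float = 0.01, runner=None) -> SensitivityMatrix:
    """Centered-difference sensitivity on log-parameters around ``params``.

    For each parameter two steady-state simulations are run at
    ``log theta +/- h``; each column is ``(y+ - y-) / (2h)``.  Perturbed
    runs are warm-started from the baseline's converged state.
    """
    runner = runner or _default_runner
    _, y_base = runner(params)
    cols = []
    for name in parameters:
        theta = params[name]
        if theta <= 0:
            raise SensitivityError(f"log-scale perturbation undefined for {name} <= 0")
        ys = []
        for sign in (+1.0, -1.0):
            pert = params.copy()
            pert[name] = float(np.exp(np.log(theta) + sign * h))
            try:
                y, _ = runner(pert, y0=y_base)
            except Exception as exc:
                raise SensitivityError(
                    f"perturbed simulation failed for parameter {name}") from exc
            ys.append(y)
        cols.append((ys[0] - ys[1]) / (2.0 * h))
    return SensitivityMatrix(S=np.column_stack(cols), parameters=tuple(parameters),
                             animal_id=params.animal_id, h=h)


@dataclass
class RankingTable:
    """Per-animal normalized scalar sensitivities and the group ranking."""

    table: pd.DataFrame          # columns: animal, parameter, normalized_sensitivity
    group_mean: pd.Series        # parameter -> mean normalized sensitivity
    rank_order: tuple            # parameters, most to least influential
    influential: tuple           # parameters above threshold (on the group mean)
    threshold: float = SENSITIVITY_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["rank"] = df["parameter"].map(
            {p: i + 1 for i, p in enumerate(self.rank_order)})
        df["influential"] = df["parameter"].isin(self.influential)
        return df.sort_values(["animal", "rank"]).reset_index(drop=True)


def normalize_and_rank(matrices, threshold: float = SENSITIVITY_THRESHOLD) -> RankingTable:
    """Column-norm scalar sensitivities, per-animal max-normalized, group-ranked."""
    if isinstance(matrices, SensitivityMatrix):
        matrices = [matrices]
    rows = []
    for m in matrices:
        norms = np.linalg.norm(m.S, axis=0)
        peak = norms.max()
        if peak == 0.0:
            raise SensitivityError(f"all-zero sensitivity matrix for {m.animal_id!r}")
        for p, s in zip(m.parameters, norms / peak):
            rows.append({"animal": m.animal_id, "parameter": p,
                         "normalized_sensitivity": float(s)})
    table = pd.DataFrame(rows)
    group = table.groupby("parameter")["normalized_sensitivity"].mean()
    order = tuple(group.sort_values(ascending=False).index)
    influential = tuple(p for p in order if group[p] > threshold)
    return RankingTable(table=table, group_mean=group, rank_order=order,
                        influential=influential, threshold=threshold)


def fim_condition(S: np.ndarray) -> float:
    """Condition number of the approximate Fisher information matrix S^T S.

    Rank-deficient matrices report infinity (subset rejected).
    """
    S = np.asarray(S, dtype=float)
    F = S.T @ S
    sv = np.linalg.svd(F, compute_uv=False)
    if sv[-1] <= sv[0] * np.finfo(float).eps * max(F.shape):
        return np.inf
    return float(sv[0] / sv[-1])


def select_parameter_subset(ranking: RankingTable, matrices,
                            limit: float = FIM_CONDITION_LIMIT) -> tuple:
    """Influential parameters harmonized across conditions, FIM-screened.

    Starts from the parameters above threshold on the group-mean ranking,
    drops the borderline systemic compliances C_SA / C_SV (retained in only
    one condition in the study regime, and only marginally), and verifies
    that the remaining subset passes the Fisher-information conditioning
    screen for every animal provided.
    """
    if isinstance(matrices, SensitivityMatrix):
        matrices = [matrices]
    subset = [p for p in ranking.influential if p not in ("C_SA", "C_SV")]
    if not subset:
        raise SensitivityError("no parameters above the sensitivity threshold")
    # stable presentation order: calibration convention first
    subset = tuple(sorted(subset, key=lambda p: (CALIBRATION_SUBSET.index(p)
                                                 if p in CALIBRATION_SUBSET else 99)))
    for m in matrices:
        idx = [m.parameters.index(p) for p in subset]
        cond = fim_condition(m.S[:, idx])
        if not cond < limit:
            raise SensitivityError(
                f"subset fails the FIM conditioning screen for {m.animal_id!r}: "
                f"cond = {cond:.3g}")
    return subset
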