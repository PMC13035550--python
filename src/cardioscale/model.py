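"""Model / Results facade over parameterization, calibration and metrics.

``CardioPulmonaryModel`` is constructed from one animal's data (an
:class:`~cardioscale.parameterization.AnimalRecord` or a preprocessed
:class:`~cardioscale.data_prep.PreparedData` plus a record); ``fit()`` runs
the multistart pressure-volume calibration of the influential parameter
subset and returns a :class:`CardioPulmonaryResults` carrying the
calibrated parameter set, the per-start audit trail, simulation and
derived-metric helpers, and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .calibration import CalibrationResult, multistart_calibrate
from .data_prep import PreparedData
from .heart import CycleSeries, run_to_steady_state
from .metrics import MetricsRecord, compute_metrics
from .parameterization import (AnimalRecord, ParameterSet, apply_hyperoxia_modifiers,
                               nominal_parameters)
from .sensitivity import CALIBRATION_SUBSET

__all__ = ["CardioPulmonaryModel", "CardioPulmonaryResults"]


class CardioPulmonaryModel:
    """Subject-specific multiscale heart + circulation model bound to one animal.

    Parameters
    ----------
    data : PreparedData or AnimalRecord
        Calibration data.  A bare record uses schematic traces built from
        its static octet; preprocessed waveforms are used as-is.
    record : AnimalRecord, optional
        Required when ``data`` is a PreparedData, to build the nominal
        parameterization.
    apply_condition_modifiers : bool
        Apply the hyperoxia parameter modifiers when the record's
        condition is Hx (default True).
    """

    def __init__(self, data, record: Optional[AnimalRecord] = None,
                 apply_condition_modifiers: bool = True, pi_sign: str = "text"):
        if isinstance(data, AnimalRecord):
            self.record = data
            self.data = PreparedData.from_record(data)
        else:
            if record is None:
                raise ValueError("record is required when passing PreparedData")
            self.record = record
            self.data = data
        base = nominal_parameters(self.record)
        if apply_condition_modifiers and self.record.condition == "Hx":
            base = apply_hyperoxia_modifiers(base, pi_sign=pi_sign)
        base.T = self.data.T
        self.nominal = base
        self.subset = tuple(CALIBRATION_SUBSET)

    @classmethod
    def from_record(cls, record: AnimalRecord, **kw) -> "CardioPulmonaryModel":
        return cls(record, **kw)

    def simulate(self, params: Optional[ParameterSet] = None, **kw) -> CycleSeries:
        """Steady-state cycle at the given (default nominal) parameters."""
        return run_to_steady_state(params or self.nominal, **kw)

    def fit(self, n_starts: int = 20, seed: Optional[int] = None,
            max_nfev: int = 2000, tol: float = 1e-6, subset=None,
            sim_opts: Optional[dict] = None) -> "CardioPulmonaryResults":
        """Multistart bounded least-squares calibration of the parameter subset."""
        subset = tuple(subset or self.subset)
        result = multistart_calibrate(self.data, self.nominal, subset=subset,
                                      n_starts=n_starts, seed=seed,
                                      max_nfev=max_nfev, tol=tol, sim_opts=sim_opts)
        return CardioPulmonaryResults(self, result)


class CardioPulmonaryResults:
    """Calibrated model: estimates, fit quality, simulation and metrics."""

    def __init__(self, model: CardioPulmonaryModel, calibration: CalibrationResult):
        self.model = model
        self.calibration = calibration
        self.params: ParameterSet = calibration.parameter_set(model.nominal)
        self._cycle: Optional[CycleSeries] = None
        self._metrics: Optional[MetricsRecord] = None

    @property
    def theta(self) -> dict:
        return dict(self.calibration.theta)

    @property
    def J(self) -> float:
        return self.calibration.J

    def simulate(self, **kw) -> CycleSeries:
        """Steady-state cycle at the calibrated optimum (cached)."""
        if self._cycle is None or kw:
            cycle = run_to_steady_state(self.params, **kw)
            if kw:
                return cycle
            self._cycle = cycle
        return self._cycle

    def metrics(self) -> MetricsRecord:
        """Derived physiologic metrics at the calibrated optimum (cached)."""
        if self._metrics is None:
            self._metrics = compute_metrics(self.simulate(), self.params,
                                            animal_id=self.model.record.id,
                                            condition=self.model.record.condition)
        return self._metrics

    def start_spread(self) -> dict:
        """Dispersion of converged costs across multistart solutions."""
        js = [s["J"] for s in self.calibration.starts if s["success"]]
        return {"n": len(js), "min": float(np.min(js)), "median": float(np.median(js)),
                "max": float(np.max(js))}

    def summary(self) -> str:
        """Human-readable calibration report."""
        rec = self.model.record
        c = self.calibration
        lines = [
            "Cardiopulmonary model calibration",
            "=" * 64,
            f"animal: {rec.id}   condition: {rec.condition}   sex: {rec.sex}",
            f"bodyweight: {rec.BW:.1f} g   period: {self.model.data.T * 1e3:.1f} ms",
            f"cost J = {c.J:.4g}   starts: {len(c.starts)} "
            f"({sum(s['success'] for s in c.starts)} converged)",
            "-" * 64,
            f"{'parameter':<14}{'nominal':>12}{'estimate':>12}{'ratio':>8}",
        ]
        for name in c.subset:
            nom, est = c.nominal[name], c.theta[name]
            lines.append(f"{name:<14}{nom:>12.4g}{est:>12.4g}{est / nom:>8.3f}")
        lines.append("-" * 64)
        o = self.simulate().octet
        d = self.model.data.octet
        lines.append(f"{'endpoint':<10}{'data':>10}{'model':>10}")
        for k in ("EDV_LV", "ESV_LV", "EDP_LV", "ESP_LV",
                  "EDV_RV", "ESV_RV", "EDP_RV", "ESP_RV"):
            lines.append(f"{k:<10}{d[k]:>10.2f}{o[k]:>10.2f}")
        blocks = " ".join(f"{k}={v:.3g}" for k, v in c.block_norms.items())
        lines.append(f"residual block norms: {blocks}")
        return "\n".join(lines)
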