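"""Shared fixtures: group-average animals, nominal models, steady cycles."""

import numpy as np
import pytest

from cardioscale.parameterization import (AnimalRecord, apply_hyperoxia_modifiers,
                                          nominal_parameters)


def nx_group_average_record() -> AnimalRecord:
    """Control group-average hemodynamics (bodyweight g, period s, uL, mmHg)."""
    return AnimalRecord(id="nx_avg", condition="Nx", sex="M", BW=49.9, T=0.177,
                        SV=28.0, ESV_LV=16.0, ESV_RV=24.0, EDP_LV=4.4, EDP_RV=2.9,
                        ESP_LV=65.0, ESP_RV=26.0)


def hx_group_average_record() -> AnimalRecord:
    """Hyperoxia group-average hemodynamics."""
    return AnimalRecord(id="hx_avg", condition="Hx", sex="M", BW=53.4, T=0.178,
                        SV=28.0, ESV_LV=18.0, ESV_RV=23.0, EDP_LV=5.1, EDP_RV=3.8,
                        ESP_LV=72.0, ESP_RV=38.0)


@pytest.fixture(scope="session")
def nx_record():
    return nx_group_average_record()


@pytest.fixture(scope="session")
def hx_record():
    return hx_group_average_record()


@pytest.fixture(scope="session")
def nominal_nx(nx_record):
    return nominal_parameters(nx_record)


@pytest.fixture(scope="session")
def nominal_hx(hx_record):
    p = nominal_parameters(hx_record)
    return apply_hyperoxia_modifiers(p)


@pytest.fixture(scope="session")
def nx_cycle(nominal_nx):
    """Steady-state cycle of the control group-average model (shared, costly)."""
    from cardioscale.heart import run_to_steady_state
    return run_to_steady_state(nominal_nx, tol=1e-3, rtol=1e-6)


@pytest.fixture(scope="session")
def hx_cycle(nominal_hx):
    """Hx group-average steady cycle with elevated pulmonary resistance.

    The crossbridge remodelling alone does not raise pulmonary pressure;
    the synthetic-cohort afterload convention (R_PA up, C_PA down) applies.
    """
    from cardioscale.cohort import apply_hx_afterload
    from cardioscale.heart import run_to_steady_state
    p = nominal_hx.copy()
    rec = hx_group_average_record()
    apply_hx_afterload(p, rec.SV * 1e-3 / rec.T)
    return run_to_steady_state(p, tol=1e-3, rtol=1e-6, max_cycles=60)


@pytest.fixture(scope="session")
def force_pca_pair(nominal_nx, nominal_hx):
    """(Nx curve, Hx curve) of the isolated RV-myofiber force-pCa experiment."""
    from cardioscale.sarcomere import simulate_force_pca
    nx = simulate_force_pca(nominal_nx.crossbridge_params("RV"),
                            nominal_nx.myofiber_params("RV"))
    hx = simulate_force_pca(nominal_hx.crossbridge_params("RV"),
                            nominal_hx.myofiber_params("RV"))
    return nx, hx


@pytest.fixture(scope="session")
def subset_sensitivity(nominal_nx):
    """Sensitivity matrix over the ten-parameter calibration subset (shared)."""
    from cardioscale.sensitivity import CALIBRATION_SUBSET, local_sensitivity
    return local_sensitivity(nominal_nx, parameters=CALIBRATION_SUBSET)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
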