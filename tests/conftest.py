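import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from apixpbpk.compound import apixaban, compute_partition_coefficients
from apixpbpk.engine import DosingRegimen, default_time_grid, simulate_individual
from apixpbpk.nca import run_nca
from apixpbpk.physiology import build_reference_individual

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_adult():
    return build_reference_individual(30.0, "male", 82.0, 180.0)


@pytest.fixture(scope="session")
def apix():
    return apixaban()


@pytest.fixture(scope="session")
def apix_kp(apix, reference_adult):
    return compute_partition_coefficients(apix, reference_adult)


@pytest.fixture(scope="session")
def adult_10mg_profile(reference_adult, apix, apix_kp):
    """Long single-dose simulation of the reference adult (10 mg oral)."""
    regimen = DosingRegimen(dose_mg=10.0, n_doses=1, interval_h=24.0, duration_h=720.0)
    return simulate_individual(
        reference_adult, apix, apix_kp, regimen, default_time_grid(720.0, 0.1)
    )


@pytest.fixture(scope="session")
def adult_10mg_auc_inf(adult_10mg_profile):
    return run_nca(adult_10mg_profile).auc_0_inf_ng_h_per_ml


def simulated_auc_inf(phys, cmp, dose_mg=10.0, duration_h=720.0, step_h=0.1):
    """AUC(0-inf) of a single oral dose for arbitrary physiology/compound."""
    kp = compute_partition_coefficients(cmp, phys)
    regimen = DosingRegimen(dose_mg=dose_mg, n_doses=1, interval_h=24.0, duration_h=duration_h)
    profile = simulate_individual(phys, cmp, kp, regimen, default_time_grid(duration_h, step_h))
    return run_nca(profile).auc_0_inf_ng_h_per_ml
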