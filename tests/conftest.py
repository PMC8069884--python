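import numpy as np
import pytest

import insupop as ip


@pytest.fixture(scope="session")
def reference_model():
    """Fixed effects, model spec and random-effect spec of the selected
    variability model at its reference estimates."""
    return ip.reference_model11()


@pytest.fixture(scope="session")
def typical_params():
    return ip.PKParams(tau=5.62, VI=0.135, alpha=0.0155, ka1=0.000134, ka2=0.0128, ke=0.113)


@pytest.fixture(scope="session")
def study2_error():
    return ip.ErrorParams(a=2.33, b=0.0516, study="study2")


@pytest.fixture(scope="session")
def small_trial(reference_model):
    """A reduced three-study synthetic trial (12 subjects per study) for
    fast end-to-end checks; LLOQ censoring disabled so estimators see the
    complete design."""
    theta, spec, respec = reference_model
    designs = [
        ip.StudyDesign(
            study_id=d.study_id, n_subjects=12, dose_amount=d.dose_amount,
            dose_per_kg=d.dose_per_kg, schedule=d.schedule, lloq=d.lloq,
            error=d.error, cov_mean=d.cov_mean, cov_sd=d.cov_sd,
        )
        for d in ip.default_designs()
    ]
    return ip.simulate_trial(designs, theta, spec, respec, seed=424, censor=False)


@pytest.fixture(scope="session")
def small_fit(small_trial, reference_model):
    """A fast SAEM fit of the reduced trial (shared across diagnostic tests)."""
    _, spec, _ = reference_model
    cfg = ip.FitConfig(
        seed=7, n_exploration=120, n_smoothing=80, mh_per_iteration=2,
        n_posterior=150, posterior_burn=50, refine_rounds=4, refine_maxiter=8,
    )
    return ip.saem_fit(small_trial.dataset, spec, cfg)
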