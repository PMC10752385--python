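import numpy as np
import pytest

from nlpsens import CohortSpec, ConfounderSpec, ModelSpec, generate_cohort


@pytest.fixture(scope="session")
def survival_cohort():
    """Well-specified survival cohort: true HR 0.57, one confounder."""
    spec = CohortSpec(
        n_subjects=2000,
        outcome_family="survival",
        true_exposure_effect=np.log(0.57),
        baseline=0.1,
        exposure_prevalence=0.2,
        censoring_rate=0.2,
        confounders=[ConfounderSpec("age", "normal", (0.0, 1.0), 0.3)],
        sensitivity=0.95,
        specificity=0.98,
        seed=11,
    )
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def binary_cohort():
    """Logistic cohort: true OR 3, one binary confounder."""
    spec = CohortSpec(
        n_subjects=3000,
        outcome_family="binary",
        true_exposure_effect=np.log(3.0),
        baseline=-1.0,
        exposure_prevalence=0.3,
        confounders=[ConfounderSpec("comorbidity", "bernoulli", (0.4,), 0.5)],
        sensitivity=0.9,
        specificity=0.95,
        seed=12,
    )
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Mixed-model cohort: fixed effect -1.43, random intercepts."""
    spec = CohortSpec(
        n_subjects=600,
        outcome_family="longitudinal",
        true_exposure_effect=-1.43,
        baseline=30.0,
        exposure_prevalence=0.3,
        visits_per_subject=3,
        random_intercept_sd=2.0,
        residual_sd=1.0,
        confounders=[ConfounderSpec("age", "normal", (0.0, 1.0), 0.2)],
        sensitivity=0.89,
        specificity=0.97,
        seed=13,
    )
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def cox_spec():
    return ModelSpec(family="cox", exposure="observed_exposure", confounders=["age"])


@pytest.fixture(scope="session")
def logistic_spec():
    return ModelSpec(
        family="logistic", exposure="observed_exposure", confounders=["comorbidity"]
    )


@pytest.fixture(scope="session")
def mixed_spec():
    return ModelSpec(family="linear_mixed", exposure="observed_exposure", confounders=["age"])
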