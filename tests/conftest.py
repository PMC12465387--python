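import numpy as np
import pytest

from ptfr_survkit import SurvivalCohort
from ptfr_survkit.synthetic import CohortSpec, CovariateSpec


@pytest.fixture
def toy_cohort():
    """Three subjects: events at days 10 and 20, censoring at day 5."""
    return SurvivalCohort(
        subject_id=np.arange(3),
        time_observed=[10.0, 5.0, 20.0],
        event=[1, 0, 1],
        covariates=np.empty((3, 0)),
        covariate_names=(),
    )


def exponential_spec(n=500, lam=0.005, mu=0.003, admin=365.0, beta=None, seed=0):
    """Single-covariate exponential-hazard cohort spec used across tests."""
    return CohortSpec(
        n=n,
        covariate_model={"x": CovariateSpec("truncnorm", 0.0, 1.0, -4.0, 4.0)},
        log_hazard_ratios={"x": beta} if beta else {},
        baseline_shape=1.0,
        baseline_scale=1.0 / lam,
        dropout_rate=mu,
        admin_time=admin,
        seed=seed,
    )


@pytest.fixture
def exponential_cohort():
    from ptfr_survkit import generate_cohort

    return generate_cohort(exponential_spec(n=400, beta=np.log(2), seed=11))
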