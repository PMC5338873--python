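"""Shared fixtures: cohorts and fitted parameter bundles are expensive, so they are
session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from baricea import SyntheticCohortConfig, generate_cohort
from baricea.estimation import estimate_all, fit_weibull_incidence, fit_weibull_mortality
from baricea.synthetic_ehr import WeibullTruth, default_baseline_hazards


@pytest.fixture(scope="session")
def small_cohort():
    """10,000-person cohort for estimation smoke tests and prevalence checks."""
    return generate_cohort(SyntheticCohortConfig(n_per_bmi_category=2000, seed=42))


@pytest.fixture(scope="session")
def small_params(small_cohort):
    """Full parameter bundle estimated from the small cohort."""
    return estimate_all(small_cohort)


@pytest.fixture(scope="session")
def recovery_config():
    """20,000-person recovery-test configuration: default truth except that the
    mortality comorbidity contrasts include an exact hazard ratio of 2 (diabetes)
    and an exact null (CHD)."""
    haz = default_baseline_hazards()
    d = haz["death"]
    haz["death"] = WeibullTruth(
        shape=d.shape, log_scale_intercept=d.log_scale_intercept,
        coef_sex=d.coef_sex, coef_bmi=d.coef_bmi,
        coef_comorbidity=(float(np.log(2.0)), 0.0, 1.0, 1.3),
    )
    return SyntheticCohortConfig(n_per_bmi_category=4000, seed=7, baseline_hazards=haz)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_config):
    return generate_cohort(recovery_config)


@pytest.fixture(scope="session")
def incidence_fit_20k(recovery_cohort):
    return fit_weibull_incidence(recovery_cohort, "diabetes")


@pytest.fixture(scope="session")
def mortality_fit_20k(recovery_cohort):
    return fit_weibull_mortality(recovery_cohort)
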