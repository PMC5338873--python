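"""Estimators: parameter recovery against generator truth, analytic oracles,
evidence-table invariants, cost and prevalence estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from baricea import SyntheticCohortConfig, generate_cohort
from baricea.estimation import (
    DomainError,
    EstimationError,
    WeibullFit,
    annual_probability,
    build_transition_evidence,
    estimate_depression_prevalence,
    fit_two_part_costs,
    fit_weibull_incidence,
    fit_weibull_mortality,
)
from baricea.synthetic_ehr import (
    BMI_CATEGORIES,
    EVENT_TYPES,
    Cohort,
    TwoPartTruth,
    WeibullTruth,
    default_baseline_hazards,
    generate_annual_costs,
)
import baricea._weibull as wb


def _truth_param_dict(truth: WeibullTruth, mortality: bool) -> dict[str, float]:
    d = {"log_shape": math.log(truth.shape), "log_scale": truth.log_scale_intercept,
         "age": truth.coef_age, "age_sq": truth.coef_age_sq, "sex": truth.coef_sex}
    d.update({f"bmi_{c}": v for c, v in zip(BMI_CATEGORIES[1:], truth.coef_bmi)})
    if mortality:
        d.update({f"comorb_{e}": v for e, v in zip(EVENT_TYPES, truth.coef_comorbidity)})
    return d


def test_incidence_recovery_within_3se(recovery_config, incidence_fit_20k):
    """Weibull incidence fit on 20,000 synthetic records recovers every generator
    parameter within 3 asymptotic SE."""
    fit = incidence_fit_20k
    assert fit.converged and np.isfinite(fit.log_likelihood)
    truth = _truth_param_dict(recovery_config.baseline_hazards["diabetes"], mortality=False)
    est = dict(zip(fit.param_names, fit.params))
    se = fit.se
    for name in fit.param_names:
        assert abs(est[name] - truth[name]) < 3 * se[name], name


def test_mortality_recovery_within_3se(recovery_config, mortality_fit_20k):
    """Mortality fit recovers the comorbidity log-hazard-ratios, including an exact
    HR of 2 (diabetes) and an exact null (CHD), within 3 SE."""
    fit = mortality_fit_20k
    assert fit.converged
    truth = _truth_param_dict(recovery_config.baseline_hazards["death"], mortality=True)
    est = dict(zip(fit.param_names, fit.params))
    se = fit.se
    for name in fit.param_names:
        assert abs(est[name] - truth[name]) < 3 * se[name], name
    # the null comorbidity effect is recovered as such
    assert abs(est["comorb_chd"]) < 3 * se["comorb_chd"]


def test_shape_ci_coverage_under_exponential_truth():
    """With true shape 1.0 (constant hazard), the 95% Wald CI of the fitted shape
    covers 1.0 in at least 90% of 50 small-cohort replicates."""
    haz = default_baseline_hazards()
    haz["diabetes"] = WeibullTruth(shape=1.0, log_scale_intercept=float(np.log(40.0)),
                                   coef_sex=0.3, coef_bmi=(0.2, 0.4, 0.6, 0.8))
    covered = 0
    for rep in range(50):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_per_bmi_category=300, seed=1000 + rep, baseline_hazards=haz))
        fit = fit_weibull_incidence(cohort, "diabetes")
        se = fit.se.get("log_shape")
        if se is None:
            continue
        lo, hi = math.log(fit.shape) - 1.96 * se, math.log(fit.shape) + 1.96 * se
        covered += lo <= 0.0 <= hi  # log(1.0) = 0
    assert covered >= 45  # >= 90% of 50


def test_zero_event_errors():
    haz = default_baseline_hazards()
    haz["cancer"] = WeibullTruth(shape=1.0, log_scale_intercept=15.0)  # ~no cancers
    cohort = generate_cohort(SyntheticCohortConfig(n_per_bmi_category=100, seed=2,
                                                   baseline_hazards=haz))
    with pytest.raises(EstimationError, match="cancer"):
        fit_weibull_incidence(cohort, "cancer")
    # no deaths at all
    haz2 = default_baseline_hazards()
    haz2["death"] = WeibullTruth(shape=1.0, log_scale_intercept=20.0)
    cohort2 = generate_cohort(SyntheticCohortConfig(n_per_bmi_category=60, seed=2,
                                                    baseline_hazards=haz2))
    if cohort2.persons.death_time.notna().sum() == 0:
        with pytest.raises(EstimationError, match="death"):
            fit_weibull_mortality(cohort2)


def test_unknown_event_type():
    cohort = generate_cohort(SyntheticCohortConfig(n_per_bmi_category=50, seed=0))
    with pytest.raises(DomainError):
        fit_weibull_incidence(cohort, "gout")


def test_annual_probability_exponential_closed_form():
    """Constant hazard lambda = 0.05: p = 1 - exp(-0.05) = 0.04877, exactly."""
    lam = 0.05
    fit = WeibullFit.from_truth(
        WeibullTruth(shape=1.0, log_scale_intercept=float(np.log(1 / lam))), "diabetes")
    p = annual_probability(fit, {"sex": 0, "bmi": 0}, 50.0)
    assert p == pytest.approx(1 - math.exp(-lam), abs=1e-12)
    # hazard -> 0 gives p -> 0
    tiny = WeibullFit.from_truth(WeibullTruth(shape=1.0, log_scale_intercept=30.0), "chd")
    assert annual_probability(tiny, {"sex": 0, "bmi": 0}, 50.0) == pytest.approx(0.0, abs=1e-10)


def test_annual_probability_domain():
    fit = WeibullFit.from_truth(WeibullTruth(shape=1.0, log_scale_intercept=3.0), "chd")
    for bad_age in (19.0, 99.5, 150.0):
        with pytest.raises(DomainError):
            annual_probability(fit, {"sex": 0, "bmi": 0}, bad_age)


@pytest.mark.parametrize("seed", range(6))
def test_annual_probability_quadrature_oracle(seed):
    """p = 1 - exp(-integral of the hazard over [a, a+1]) agrees with adaptive
    quadrature of the hazard itself to 1e-8, for random parameter draws."""
    rng = np.random.default_rng(seed)
    truth = WeibullTruth(
        shape=float(rng.uniform(0.6, 4.0)),
        log_scale_intercept=float(rng.uniform(2.0, 6.0)),
        coef_age=float(rng.uniform(-0.5, 0.5)),
        coef_age_sq=float(rng.uniform(-0.2, 0.2)),
        coef_sex=float(rng.uniform(-0.5, 0.5)),
        coef_bmi=tuple(rng.uniform(-0.5, 2.0, size=4)),
    )
    fit = WeibullFit.from_truth(truth, "diabetes")
    cov = {"sex": 1, "bmi": int(rng.integers(0, 5))}
    age = float(rng.uniform(20.0, 98.0))
    lp = float(truth.linear_predictor(cov["sex"], cov["bmi"]))

    def hazard(a):
        return math.exp(wb.log_baseline_hazard(a, truth.shape, truth.sigma,
                                               truth.coef_age, truth.coef_age_sq) + lp)

    ref, _ = integrate.quad(hazard, age, age + 1.0, limit=400)
    expected = 1.0 - math.exp(-ref)
    got = annual_probability(fit, cov, age)
    assert got == pytest.approx(expected, abs=1e-8)


def test_annual_probability_monotone_in_positive_coefficient():
    truth = default_baseline_hazards()["diabetes"]  # BMI coefficients all positive
    fit = WeibullFit.from_truth(truth, "diabetes")
    ps = [annual_probability(fit, {"sex": 0, "bmi": b}, 50.0) for b in range(5)]
    assert all(a < b for a, b in zip(ps, ps[1:]))


def test_transition_evidence_invariants(small_cohort, small_params):
    ev = small_params.evidence
    assert ev.p_incidence.shape == (80, 2, 5, 4)
    assert ev.p_death.shape == (80, 2, 5, 5)
    assert (ev.n_at_risk >= 1.0).all() and (ev.n_by_class >= 1.0).all()
    assert ((ev.r_incidence >= 0) & (ev.r_incidence <= ev.n_at_risk[..., None])).all()
    assert ((ev.r_death >= 0) & (ev.r_death <= ev.n_by_class)).all()
    records = list(ev.records())
    assert len(records) == 80 * 2 * 5 * (4 + 5)  # exhaustive over strata x destinations
    # death probability higher for comorbid states than at-risk (positive coefficients)
    assert (ev.p_death[..., 1:] >= ev.p_death[..., :1]).all()


def test_beta_draws_from_evidence_mean(small_params):
    """Beta(r, n - r) draws have mean ~ r/n = p over 10,000 draws (the PSA's
    beta-binomial identity)."""
    ev = small_params.evidence
    ai, s, b = 45, 0, 4  # age 65, female, morbidly obese: well-populated stratum
    n = ev.n_at_risk[ai, s, b]
    r = ev.r_incidence[ai, s, b, 0]
    assert n > 50
    rng = np.random.default_rng(1)
    draws = rng.beta(r, n - r, size=10_000)
    se = draws.std() / 100.0
    assert abs(draws.mean() - r / n) < 4 * se


def test_depression_prevalence_counts():
    persons = pd.DataFrame({
        "person_id": range(100), "event_type": ["none"] * 100,
        "depressed": [False] * 100,
    })
    cohort = Cohort(persons, pd.DataFrame(columns=["person_id", "year_index", "cost",
                                                   "state_class"]))
    assert estimate_depression_prevalence(cohort, "at_risk").prevalence == 0.0
    persons2 = persons.copy()
    persons2.loc[:24, "depressed"] = True
    dp = estimate_depression_prevalence(Cohort(persons2, cohort.costs), "at_risk")
    assert dp.prevalence == 0.25
    assert (dp.numerator, dp.denominator) == (25, 100)
    with pytest.raises(EstimationError):
        estimate_depression_prevalence(cohort, "stroke")


def test_depression_prevalence_recovery(small_cohort):
    cfg = SyntheticCohortConfig(n_per_bmi_category=2000, seed=42)
    for cls in ("at_risk", "diabetes"):
        dp = estimate_depression_prevalence(small_cohort, cls)
        truth = cfg.depression_prevalence[cls]
        se = math.sqrt(truth * (1 - truth) / dp.denominator)
        assert abs(dp.prevalence - truth) < 3 * se


def _cost_cohort(truth: TwoPartTruth, n_years: int, seed: int) -> Cohort:
    rng = np.random.default_rng(seed)
    vals = generate_annual_costs(truth, n_years, rng)
    persons = pd.DataFrame({"person_id": [0], "event_type": ["none"], "depressed": [False],
                            "entry_age": [40.0], "sex": [0]})
    costs = pd.DataFrame({"person_id": np.zeros(n_years, dtype=int),
                          "year_index": np.arange(n_years),
                          "cost": vals, "state_class": "at_risk"})
    return Cohort(persons, costs)


def test_two_part_costs_all_zero():
    cohort = _cost_cohort(TwoPartTruth(0.0, 500.0), 50, 1)
    est = fit_two_part_costs(cohort, "at_risk")
    assert est.expected_annual_cost == 0.0
    assert not est.gamma_valid


def test_two_part_costs_recovery():
    """Truth p = 0.8, positive mean 1,000: expected cost recovers 800 within 2 SE at
    10,000 person-years, and the gamma shape recovers within 3 SE."""
    truth = TwoPartTruth(0.8, 1000.0, gamma_shape=1.5)
    cohort = _cost_cohort(truth, 10_000, 3)
    est = fit_two_part_costs(cohort, "at_risk")
    vals = cohort.costs.cost.to_numpy()
    se = vals.std() / math.sqrt(vals.size)
    assert abs(est.expected_annual_cost - 800.0) < 2 * se
    # asymptotic SE of the gamma ML shape: sqrt(1 / (n (psi'(k) - 1/k)))
    from scipy.special import polygamma
    npos = est.successes
    k = truth.gamma_shape
    se_shape = 1.0 / math.sqrt(npos * (polygamma(1, k) - 1.0 / k))
    assert abs(est.gamma_shape - k) < 3 * se_shape


def test_two_part_costs_sparse_error():
    cohort = _cost_cohort(TwoPartTruth(0.5, 100.0), 5, 0)
    with pytest.raises(EstimationError):
        fit_two_part_costs(cohort, "at_risk")


def test_weibull_fit_agrees_with_lifelines_oracle():
    """On the no-age-modulation submodel our PH fit must agree with an independent
    AFT Weibull fit (lifelines, left-truncated): beta_PH = -shape * beta_AFT."""
    lifelines = pytest.importorskip("lifelines")
    haz = default_baseline_hazards()
    haz["diabetes"] = WeibullTruth(shape=1.3, log_scale_intercept=5.5,
                                   coef_sex=0.3, coef_bmi=(0.6, 1.2, 1.8, 2.4))
    cfg = SyntheticCohortConfig(n_per_bmi_category=2500, seed=21, baseline_hazards=haz)
    cohort = generate_cohort(cfg)
    ours = fit_weibull_incidence(cohort, "diabetes")

    p = cohort.persons
    end = np.where(p.event_time.notna(), p.event_time, p.exit_time)
    df = pd.DataFrame({
        "duration": end - 20.0,
        "entry": p.entry_age - 20.0,
        "event": (p.event_type == "diabetes").astype(int),
        "sex": p.sex,
    })
    for i, cat in enumerate(BMI_CATEGORIES[1:]):
        df[f"bmi{i}"] = (p.bmi_category == cat).astype(int)
    aft = lifelines.WeibullAFTFitter()
    aft.fit(df, duration_col="duration", event_col="event", entry_col="entry")
    rho = float(np.exp(aft.params_[("rho_", "Intercept")]))
    ours_beta = dict(zip(ours.param_names, ours.params))
    for col, name in [("sex", "sex")] + [(f"bmi{i}", f"bmi_{c}")
                                         for i, c in enumerate(BMI_CATEGORIES[1:])]:
        beta_ph = -rho * float(aft.params_[("lambda_", col)])
        assert ours_beta[name] == pytest.approx(beta_ph, abs=0.08), name
    assert ours.shape == pytest.approx(rho, rel=0.1)
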