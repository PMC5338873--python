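"""Subgroup, sensitivity and commissioning-projection runs.

Each scenario is a configured end-to-end pipeline run: an entry-population filter
(sex, age band, deprivation quintile, BMI category, diabetes-only), a procedure-cost
multiplier, an optional global decay of the intervention effect, and a reporting
discount rate.  Subgroup runs reuse the full-cohort parameter estimates, predicting
within the subgroup's strata (the evidence grid is already stratified by age, sex and
BMI).  Deprivation quintile is carried as an entry-population label: the synthetic
cohort draws deprivation independently of risk, so least/most-deprived runs differ
only by Monte-Carlo noise unless the user supplies deprivation-dependent inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .economics import CEAResult, summarize
from .estimation import ModelParameters
from .model_core import InitialPopulationSpec, InterventionSpec, default_utility_table
from .simulation import SimulationConfig, run_psa
from .synthetic_ehr import BMI_CATEGORIES

AGE_BAND_CHOICES = {"20-34": (20, 34), "35-54": (35, 54), "55-74": (55, 74)}


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One configured pipeline run."""

    name: str = "base"
    sex: str | None = None                  # "male" | "female"
    age_band: str | None = None             # "20-34" | "35-54" | "55-74"
    imd: str | None = None                  # "least" | "most" (deprived)
    bmi: str = ">=40"                       # ">=40" | "35-39"
    diabetes_only: bool = False
    cost_multiplier: float = 1.0            # 1.0 | 1.5 | 2.0 | 0.0
    decay_exponent: float | None = None     # None | -0.25 | -0.50
    discount_rate: float = 0.035            # 0 | 0.015 | 0.035
    n_sims: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.sex not in (None, "male", "female"):
            raise ScenarioError(f"unknown sex filter {self.sex!r}")
        if self.age_band is not None and self.age_band not in AGE_BAND_CHOICES:
            raise ScenarioError(f"unknown age band {self.age_band!r}")
        if self.imd not in (None, "least", "most"):
            raise ScenarioError(f"unknown deprivation filter {self.imd!r}")
        if self.bmi not in (">=40", "35-39"):
            raise ScenarioError(f"unsupported entry BMI category {self.bmi!r}")
        if self.discount_rate not in (0.0, 0.015, 0.035):
            raise ScenarioError(f"unsupported discount rate {self.discount_rate!r}")


NAMED_SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec(name="base"),
    "bmi-35-39": ScenarioSpec(name="bmi-35-39", bmi="35-39"),
    "male": ScenarioSpec(name="male", sex="male"),
    "female": ScenarioSpec(name="female", sex="female"),
    "age-20-34": ScenarioSpec(name="age-20-34", age_band="20-34"),
    "age-35-54": ScenarioSpec(name="age-35-54", age_band="35-54"),
    "age-55-74": ScenarioSpec(name="age-55-74", age_band="55-74"),
    "least-deprived": ScenarioSpec(name="least-deprived", imd="least"),
    "most-deprived": ScenarioSpec(name="most-deprived", imd="most"),
    "diabetes-bmi-40": ScenarioSpec(name="diabetes-bmi-40", diabetes_only=True),
    "cost-50pct-higher": ScenarioSpec(name="cost-50pct-higher", cost_multiplier=1.5),
    "cost-100pct-higher": ScenarioSpec(name="cost-100pct-higher", cost_multiplier=2.0),
    "zero-procedure-cost": ScenarioSpec(name="zero-procedure-cost", cost_multiplier=0.0),
    "decay-0.25": ScenarioSpec(name="decay-0.25", decay_exponent=-0.25),
    "decay-0.50": ScenarioSpec(name="decay-0.50", decay_exponent=-0.50),
}


def initial_population_for(spec: ScenarioSpec,
                           base: InitialPopulationSpec | None = None) -> InitialPopulationSpec:
    """Entry population implied by a scenario's filters (per-1,000 reporting makes
    the absolute size immaterial; composition is what matters)."""
    pop = base or InitialPopulationSpec()
    if spec.sex == "male":
        pop = replace(pop, n_men=pop.total, n_women=0)
    elif spec.sex == "female":
        pop = replace(pop, n_men=0, n_women=pop.total)
    if spec.age_band is not None:
        pop = replace(pop, age_range=AGE_BAND_CHOICES[spec.age_band])
    if spec.bmi != pop.bmi_category:
        pop = replace(pop, bmi_category=spec.bmi)
    if spec.diabetes_only:
        pop = replace(pop, disease_counts={"diabetes": pop.total})
    return pop


def run_scenario(spec: ScenarioSpec, params: ModelParameters,
                 intervention: InterventionSpec | None = None,
                 base_population: InitialPopulationSpec | None = None) -> tuple[CEAResult, dict]:
    """Execute the full pipeline under a scenario and return (CEAResult, table row)."""
    base_int = intervention or InterventionSpec()
    iv = replace(base_int, procedure_cost_multiplier=spec.cost_multiplier,
                 effect_decay_exponent=spec.decay_exponent)
    config = SimulationConfig(
        params=params,
        initial_spec=initial_population_for(spec, base_population),
        intervention=iv,
        utility_table=default_utility_table(),
    )
    runs = run_psa(spec.n_sims, spec.seed, config)
    res = summarize(runs, base_rate=spec.discount_rate)
    r = spec.discount_rate
    row = {
        "condition": spec.name,
        "surgery_total_cost_millions": round(res.total_cost[r]["surgery"].mean, 2),
        "surgery_total_qalys": round(res.total_qalys[r]["surgery"].mean, 0),
        "incremental_cost_millions": round(res.inc_cost[r].mean, 2),
        "incremental_qalys": round(res.inc_qalys[r].mean, 0),
        "cost_per_qaly": round(res.icer_of_means[r], 0),
        "cost_per_qaly_ci_low": None if res.icer[r].ci is None else round(res.icer[r].ci[0], 0),
        "cost_per_qaly_ci_high": None if res.icer[r].ci is None else round(res.icer[r].ci[1], 0),
    }
    return res, row


@dataclass(frozen=True)
class CommissioningInputs:
    """Inputs for a health-care-commissioning-organisation projection.

    Prevalences must be supplied by the user (e.g. from national survey estimates for
    the organisation's population); none are bundled.  Sex keys are "female"/"male".
    """

    morbid_obesity_prevalence: Mapping[str, float]
    diabetes_prevalence_given_morbid_obesity: Mapping[str, float]
    population: int = 250_000
    sex_split: Mapping[str, float] = field(default_factory=lambda: {"female": 0.5, "male": 0.5})
    n_procedures: int = 1_000
    proportion_in_diabetics: float = 0.5

    def __post_init__(self):
        for m in (self.morbid_obesity_prevalence, self.diabetes_prevalence_given_morbid_obesity):
            for k in ("female", "male"):
                if k not in m:
                    raise ScenarioError(f"missing prevalence for {k!r}")
                if not 0.0 <= m[k] <= 1.0:
                    raise ScenarioError("prevalences must lie in [0, 1]")


def _diabetes_cases_prevented_10y(params: ModelParameters, n_nondiabetic: float,
                                  intervention: InterventionSpec,
                                  population: InitialPopulationSpec) -> float:
    """Expected reduction in new diabetes diagnoses over 10 years among the
    non-diabetic operated, from the evidence-mean incidence at the entry ages."""
    from .model_core import _entry_age_pmf, BMI_CATEGORIES as _BMI
    ev = params.evidence
    pmf = _entry_age_pmf(population)
    lo = population.age_range[0]
    b = _BMI.index(population.bmi_category)
    ai = np.arange(lo, lo + len(pmf)) - int(ev.ages[0])
    p = 0.5 * (ev.p_incidence[ai, 0, b, 0] + ev.p_incidence[ai, 1, b, 0])
    p_bar = float((pmf * p).sum())
    rr = intervention.rr_incidence["diabetes"][0]
    risk10_base = 1.0 - (1.0 - p_bar) ** 10
    risk10_surg = 1.0 - (1.0 - rr * p_bar) ** 10
    return n_nondiabetic * (risk10_base - risk10_surg)


def commissioning_projection(inputs: CommissioningInputs, cea: CEAResult,
                             params: ModelParameters | None = None,
                             intervention: InterventionSpec | None = None,
                             population: InitialPopulationSpec | None = None) -> dict:
    """Project counts and lifetime economics for a commissioning population."""
    iv = intervention or InterventionSpec()
    pop = population or InitialPopulationSpec()
    n_by_sex = {s: inputs.population * inputs.sex_split[s] for s in ("female", "male")}
    mo = {s: n_by_sex[s] * inputs.morbid_obesity_prevalence[s] for s in n_by_sex}
    dm = {s: mo[s] * inputs.diabetes_prevalence_given_morbid_obesity[s] for s in mo}
    k = inputs.n_procedures / 1000.0
    r = cea.base_rate
    n_diabetic_ops = inputs.n_procedures * inputs.proportion_in_diabetics
    out = {
        "population_20_74": inputs.population,
        "n_morbid_obesity": round(sum(mo.values())),
        "n_morbid_obesity_women": round(mo["female"]),
        "n_morbid_obesity_men": round(mo["male"]),
        "n_morbid_obesity_diabetes": round(sum(dm.values())),
        "procedure_cost_millions": inputs.n_procedures * iv.total_procedure_cost / 1e6,
        "lifetime_incremental_cost_millions": round(cea.inc_cost[r].mean * k, 2),
        "lifetime_qaly_gain": round(cea.inc_qalys[r].mean * k),
        "nmb_millions_30k": round(cea.nmb[30_000.0].mean * k, 2),
        "diabetes_remissions": n_diabetic_ops * iv.diabetes_remission,
    }
    if params is not None:
        prevented = _diabetes_cases_prevented_10y(
            params, inputs.n_procedures - n_diabetic_ops, iv, pop)
        out["diabetes_cases_prevented_10y"] = round(prevented)
    return out
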