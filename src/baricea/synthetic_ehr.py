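"""Synthetic primary-care cohort generator.

Emulates the statistical structure of a UK primary-care EHR extract (CPRD-like) used to
parameterise the decision model: per-person demographics, BMI category, Weibull
time-to-event comorbidity incidence and mortality, state-dependent depression flags, and
two-part (zero-inflated gamma) annual health-care costs.  Nothing here is real patient
data; the generator's "truth" parameters are the quantities the estimation module is
meant to recover.

Event-time model
----------------
Each of the four comorbidities (diabetes, CHD, stroke, cancer) and death has a
proportional-hazards Weibull hazard on the age timescale (see ``_weibull``), with
covariates sex and BMI category, and — for mortality — indicator terms for each
prevalent comorbidity.  A person enters observation at their entry age (left
truncation), is administratively censored after a lognormally distributed follow-up,
and the record closes at the earliest of censoring and death.  The first incident
comorbidity, if any, is recorded; from its onset the mortality hazard switches to the
comorbid form.  Annual costs are drawn per year of follow-up from the two-part model of
the person's current state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from ._weibull import AGE_ORIGIN, baseline_cum_hazard, baseline_inverse_grid, invert_baseline

BMI_CATEGORIES: tuple[str, ...] = ("18.5-25", "25-29", "30-34", "35-39", ">=40")
EVENT_TYPES: tuple[str, ...] = ("diabetes", "chd", "stroke", "cancer")
STATE_CLASSES: tuple[str, ...] = ("at_risk",) + EVENT_TYPES
FEMALE, MALE = 0, 1

_MAX_AGE = 110.0  # simulation horizon for event times; records censor far earlier


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class WeibullTruth:
    """True Weibull proportional-hazards parameters for one event type.

    ``coef_bmi`` holds the four log-hazard-ratio contrasts versus normal weight,
    in the order of ``BMI_CATEGORIES[1:]``; ``coef_comorbidity`` the four contrasts
    versus no comorbidity (used for mortality only), in ``EVENT_TYPES`` order.
    """

    shape: float
    log_scale_intercept: float  # log of the Weibull scale, in log-years
    coef_age: float = 0.0
    coef_age_sq: float = 0.0
    coef_sex: float = 0.0  # male vs female
    coef_bmi: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    coef_comorbidity: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ConfigurationError(f"Weibull shape must be positive, got {self.shape}")
        if len(self.coef_bmi) != 4:
            raise ConfigurationError("exactly 4 BMI contrasts required (reference = normal weight)")
        if len(self.coef_comorbidity) != 4:
            raise ConfigurationError("exactly 4 comorbidity contrasts required")

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_scale_intercept))

    def linear_predictor(self, sex, bmi_index, comorbidity_index=None):
        """lp = x'beta for sex (0/1), BMI index (0..4) and optional comorbidity (0..3)."""
        sex = np.asarray(sex)
        bmi_index = np.asarray(bmi_index)
        bmi_coefs = np.concatenate([[0.0], self.coef_bmi])
        lp = self.coef_sex * sex + bmi_coefs[bmi_index]
        if comorbidity_index is not None:
            com_coefs = np.asarray(self.coef_comorbidity)
            lp = lp + com_coefs[np.asarray(comorbidity_index)]
        return lp


@dataclass(frozen=True)
class TwoPartTruth:
    """True two-part annual-cost process: P(any cost) and the positive-cost gamma."""

    p_any_cost: float
    mean_positive_cost: float  # GBP per year
    gamma_shape: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_any_cost <= 1.0:
            raise ConfigurationError("p_any_cost must lie in [0, 1]")
        if not self.mean_positive_cost > 0:
            raise ConfigurationError("mean_positive_cost must be positive")
        if not self.gamma_shape > 0:
            raise ConfigurationError("gamma_shape must be positive")

    @property
    def expected_annual_cost(self) -> float:
        return self.p_any_cost * self.mean_positive_cost


def default_baseline_hazards() -> dict[str, WeibullTruth]:
    """Default truth: incidence and mortality hazards of plausible magnitude for a UK
    adult primary-care population, rising with age and strongly BMI-graded for diabetes.
    """
    return {
        "diabetes": WeibullTruth(
            shape=1.2, log_scale_intercept=5.87, coef_age=0.15, coef_age_sq=-0.05,
            coef_sex=0.2, coef_bmi=(0.7, 1.4, 2.0, 2.6),
        ),
        "chd": WeibullTruth(
            shape=1.5, log_scale_intercept=5.69, coef_age=0.3, coef_age_sq=0.0,
            coef_sex=0.5, coef_bmi=(0.2, 0.45, 0.7, 0.9),
        ),
        "stroke": WeibullTruth(
            shape=1.8, log_scale_intercept=5.89, coef_age=0.35, coef_age_sq=0.0,
            coef_sex=0.3, coef_bmi=(0.15, 0.3, 0.5, 0.7),
        ),
        "cancer": WeibullTruth(
            shape=2.2, log_scale_intercept=4.65, coef_age=0.2, coef_age_sq=0.0,
            coef_sex=0.1, coef_bmi=(0.05, 0.12, 0.2, 0.3),
        ),
        "death": WeibullTruth(
            shape=4.5, log_scale_intercept=float(np.log(65.0)),
            coef_sex=0.35, coef_bmi=(0.05, 0.15, 0.3, 0.5),
            coef_comorbidity=(0.6, 0.8, 1.0, 1.3),
        ),
    }


def default_depression_prevalence() -> dict[str, float]:
    return {"at_risk": 0.15, "diabetes": 0.25, "chd": 0.25, "stroke": 0.30, "cancer": 0.30}


def default_cost_truth() -> dict[str, TwoPartTruth]:
    return {
        "at_risk": TwoPartTruth(0.85, 900.0, 1.1),
        "diabetes": TwoPartTruth(0.95, 2500.0, 1.2),
        "chd": TwoPartTruth(0.95, 3000.0, 1.2),
        "stroke": TwoPartTruth(0.96, 4000.0, 1.1),
        "cancer": TwoPartTruth(0.97, 5000.0, 1.0),
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of one synthetic cohort draw.

    ``follow_up_years_median`` is the median of the lognormal administrative follow-up
    (the register window), targeting the ~5.6-year median analysis time of a 2008-2013
    primary-care extract; ``follow_up_log_sd`` reproduces its wide interquartile range.
    """

    n_per_bmi_category: int = 50_000
    seed: int = 0
    entry_age_range: tuple[float, float] = (20.0, 100.0)
    follow_up_years_median: float = 5.6
    follow_up_log_sd: float = 1.11
    baseline_hazards: Mapping[str, WeibullTruth] = field(default_factory=default_baseline_hazards)
    depression_prevalence: Mapping[str, float] = field(default_factory=default_depression_prevalence)
    cost_truth: Mapping[str, TwoPartTruth] = field(default_factory=default_cost_truth)
    bmi_categories: tuple[str, ...] = BMI_CATEGORIES
    sex_ratio: float = 0.5  # proportion male

    def __post_init__(self) -> None:
        if self.n_per_bmi_category < 0:
            raise ConfigurationError("n_per_bmi_category must be >= 0")
        if tuple(self.bmi_categories) != BMI_CATEGORIES or len(self.bmi_categories) != 5:
            raise ConfigurationError(f"bmi_categories must be the 5 ordered levels {BMI_CATEGORIES}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for cls, p in self.depression_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"depression prevalence for {cls!r} outside [0, 1]")
        lo, hi = self.entry_age_range
        if not (AGE_ORIGIN <= lo < hi):
            raise ConfigurationError("entry_age_range must satisfy 20 <= lo < hi")
        for name in EVENT_TYPES + ("death",):
            if name not in self.baseline_hazards:
                raise ConfigurationError(f"baseline_hazards missing event type {name!r}")


@dataclass(frozen=True)
class EHRPerson:
    """One synthetic primary-care record.  Times are ages in fractional years; the
    observation interval is [entry_time, exit_time)."""

    person_id: int
    sex: int  # 0 = female, 1 = male
    entry_age: float
    imd_quintile: int
    bmi_category: str
    entry_time: float
    exit_time: float
    event_type: str  # one of EVENT_TYPES or "none"
    event_time: float | None
    death_time: float | None
    depressed: bool
    annual_costs: tuple[tuple[int, float], ...]


class Cohort:
    """A synthetic cohort: a per-person table plus a long person-year cost table."""

    def __init__(self, persons: pd.DataFrame, costs: pd.DataFrame):
        self.persons = persons
        self.costs = costs

    def __len__(self) -> int:
        return len(self.persons)

    def iter_persons(self) -> Iterator[EHRPerson]:
        cost_groups = {pid: grp for pid, grp in self.costs.groupby("person_id")}
        for row in self.persons.itertuples(index=False):
            grp = cost_groups.get(row.person_id)
            costs = tuple(
                (int(y), float(c)) for y, c in zip(grp.year_index, grp.cost)
            ) if grp is not None else ()
            yield EHRPerson(
                person_id=int(row.person_id), sex=int(row.sex),
                entry_age=float(row.entry_age), imd_quintile=int(row.imd_quintile),
                bmi_category=str(row.bmi_category),
                entry_time=float(row.entry_time), exit_time=float(row.exit_time),
                event_type=str(row.event_type),
                event_time=None if pd.isna(row.event_time) else float(row.event_time),
                death_time=None if pd.isna(row.death_time) else float(row.death_time),
                depressed=bool(row.depressed), annual_costs=costs,
            )

    def to_csv(self, path) -> None:
        """One row per person; annual costs packed as 'year:cost;...' to 2 dp."""
        df = self.persons.copy()
        packed = (
            self.costs.assign(
                item=lambda d: d.year_index.astype(str) + ":" + d.cost.map("{:.2f}".format)
            )
            .groupby("person_id")["item"]
            .agg(";".join)
        )
        df["annual_costs"] = df["person_id"].map(packed).fillna("")
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        packed = df.pop("annual_costs").fillna("")
        pids, years, vals = [], [], []
        for pid, s in zip(df["person_id"], packed):
            if not s:
                continue
            for item in s.split(";"):
                y, c = item.split(":")
                pids.append(pid)
                years.append(int(y))
                vals.append(float(c))
        costs = pd.DataFrame({"person_id": pids, "year_index": years, "cost": vals})
        costs = _attach_cost_classes(df, costs)
        return cls(df, costs)


def _attach_cost_classes(persons: pd.DataFrame, costs: pd.DataFrame) -> pd.DataFrame:
    """Recompute each cost-year's state class from the person record."""
    p = persons.set_index("person_id")
    entry = p.loc[costs.person_id, "entry_age"].to_numpy()
    ev_time = p.loc[costs.person_id, "event_time"].to_numpy()
    ev_type = p.loc[costs.person_id, "event_type"].to_numpy()
    mid = entry + costs.year_index.to_numpy() + 0.5
    post = ~pd.isna(ev_time) & (mid >= np.nan_to_num(ev_time, nan=np.inf))
    costs = costs.copy()
    costs["state_class"] = np.where(post, ev_type, "at_risk")
    return costs


def _event_age_draws(truth: WeibullTruth, lp, entry_age, exponentials):
    """Vectorised left-truncated inverse-transform draw of event ages."""
    grid = None
    if truth.coef_age != 0.0 or truth.coef_age_sq != 0.0:
        grid = baseline_inverse_grid(truth.shape, truth.sigma, truth.coef_age, truth.coef_age_sq,
                                     age_max=_MAX_AGE)
        h_entry = np.interp(entry_age, grid[0], grid[1])
    else:
        h_entry = baseline_cum_hazard(AGE_ORIGIN, entry_age, truth.shape, truth.sigma)
    target = h_entry + exponentials * np.exp(-lp)
    return invert_baseline(target, truth.shape, truth.sigma, truth.coef_age,
                           truth.coef_age_sq, grid=grid)


def simulate_time_to_event(truth: WeibullTruth, covariates: Mapping, entry_age: float,
                           rng: np.random.Generator, u: float | None = None) -> float:
    """Draw one event age from the left-truncated Weibull.

    ``covariates``: mapping with keys ``sex`` (0/1), ``bmi`` (0..4) and optionally
    ``comorbidity`` (0..3 or None).  The draw is monotone decreasing in the uniform
    deviate ``u`` (``u -> 1`` gives an event age approaching ``entry_age``); when ``u``
    is None a deviate is taken from ``rng``.
    """
    lp = float(truth.linear_predictor(covariates.get("sex", 0), covariates.get("bmi", 0),
                                      None if covariates.get("comorbidity") is None
                                      else covariates["comorbidity"]))
    e = -np.log(u) if u is not None else rng.exponential()
    return float(_event_age_draws(truth, lp, np.asarray(float(entry_age)), e))


def generate_annual_costs(truth: TwoPartTruth, n_years: int, rng: np.random.Generator) -> np.ndarray:
    """Two-part annual cost draws: zero w.p. 1 - p_any_cost, else gamma with the
    configured positive-cost mean."""
    any_cost = rng.random(n_years) < truth.p_any_cost
    draws = rng.gamma(truth.gamma_shape, truth.mean_positive_cost / truth.gamma_shape,
                      size=n_years)
    return np.where(any_cost, draws, 0.0)


def _entry_ages(n: int, age_range: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    # Adult-register-like age profile: right-skewed beta over the entry range, so the
    # elderly (with short survival) are present but not a fifth of the cohort.
    lo, hi = age_range
    return lo + (hi - lo) * rng.beta(2.0, 4.0, size=n)


def _calibrate_censor_median(target: float, censor_mults: np.ndarray,
                             time_to_endpoint: np.ndarray) -> float:
    """Median m of the administrative-censoring lognormal such that the *analysis time*
    min(censoring, first event or death) has median ``target``.

    Records end at the earliest of record end, comorbidity onset and death, so the
    administrative window must be somewhat longer than the target analysis-time median;
    the required inflation depends on the event/death hazards and is solved here by
    bisection on the cohort's own simulated endpoint times.
    """
    def median_at(m: float) -> float:
        return float(np.median(np.minimum(m * censor_mults, time_to_endpoint)))

    lo, hi = target * 0.5, target * 50.0
    if median_at(hi) < target:  # endpoint times dominate; censoring cannot stretch further
        warnings.warn("endpoint times too short to reach the target follow-up median",
                      RuntimeWarning, stacklevel=2)
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if median_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a synthetic cohort; reproducible (bit-identical) under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_cat = config.n_per_bmi_category
    n = n_cat * 5
    if n == 0:
        persons = pd.DataFrame(columns=[
            "person_id", "sex", "entry_age", "imd_quintile", "bmi_category",
            "entry_time", "exit_time", "event_type", "event_time", "death_time", "depressed",
        ])
        costs = pd.DataFrame(columns=["person_id", "year_index", "cost", "state_class"])
        return Cohort(persons, costs)

    bmi = np.repeat(np.arange(5), n_cat)
    sex = (rng.random(n) < config.sex_ratio).astype(int)
    entry = _entry_ages(n, config.entry_age_range, rng)
    imd = rng.integers(1, 6, size=n)
    censor_mults = rng.lognormal(0.0, config.follow_up_log_sd, size=n)

    # Competing incident comorbidities from the at-risk state.
    event_ages = np.empty((4, n))
    for k, name in enumerate(EVENT_TYPES):
        truth = config.baseline_hazards[name]
        lp = truth.linear_predictor(sex, bmi)
        event_ages[k] = _event_age_draws(truth, lp, entry, rng.exponential(size=n))
    first_idx = np.argmin(event_ages, axis=0)
    first_age = event_ages[first_idx, np.arange(n)]

    # Death: comorbidity-free draw, re-drawn from onset under the comorbid hazard.
    death_truth = config.baseline_hazards["death"]
    lp_death0 = death_truth.linear_predictor(sex, bmi)
    death0 = _event_age_draws(death_truth, lp_death0, entry, rng.exponential(size=n))

    endpoint = np.minimum(first_age, death0) - entry
    m_censor = _calibrate_censor_median(config.follow_up_years_median, censor_mults, endpoint)
    follow = np.clip(m_censor * censor_mults, 0.1, 40.0)
    censor = np.minimum(entry + follow, _MAX_AGE)

    has_event = first_age < np.minimum(death0, censor)
    lp_death1 = death_truth.linear_predictor(sex, bmi, first_idx)
    death1 = _event_age_draws(death_truth, lp_death1,
                              np.where(has_event, first_age, entry),
                              rng.exponential(size=n))
    death = np.where(has_event, death1, death0)

    exit_age = np.minimum(censor, death)
    died = death <= censor
    event_time = np.where(has_event, first_age, np.nan)
    event_type = np.where(has_event, np.array(EVENT_TYPES, dtype=object)[first_idx], "none")

    state_class = np.where(has_event, event_type, "at_risk")
    prev = np.array([config.depression_prevalence[c] for c in state_class])
    depressed = rng.random(n) < prev

    persons = pd.DataFrame({
        "person_id": np.arange(n),
        "sex": sex,
        "entry_age": entry,
        "imd_quintile": imd,
        "bmi_category": np.array(config.bmi_categories, dtype=object)[bmi],
        "entry_time": entry,
        "exit_time": exit_age,
        "event_type": event_type,
        "event_time": event_time,
        "death_time": np.where(died, death, np.nan),
        "depressed": depressed,
    })

    # Per-year two-part costs in the person's current state.
    n_years = np.ceil(exit_age - entry - 1e-9).astype(int)
    n_years = np.maximum(n_years, 1)
    pid_rep = np.repeat(np.arange(n), n_years)
    offsets = np.repeat(np.cumsum(n_years) - n_years, n_years)
    year_idx = np.arange(n_years.sum()) - offsets
    mid_age = entry[pid_rep] + year_idx + 0.5
    post_event = has_event[pid_rep] & (mid_age >= np.nan_to_num(event_time, nan=np.inf)[pid_rep])
    year_class = np.where(post_event, event_type[pid_rep], "at_risk")

    cost = np.zeros(len(pid_rep))
    for cls in STATE_CLASSES:
        mask = year_class == cls
        m = int(mask.sum())
        if m:
            cost[mask] = generate_annual_costs(config.cost_truth[cls], m, rng)
    costs = pd.DataFrame({
        "person_id": pid_rep, "year_index": year_idx, "cost": cost, "state_class": year_class,
    })
    return Cohort(persons, costs)
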