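"""State space, initial population, transition rows and intervention machinery.

The decision model compares two arms — bariatric surgery vs no surgery — over a
101-state Markov structure: 2 arms x 5 BMI categories x 5 disease states (at risk,
diabetes, CHD, stroke, cancer) x 2 depression substates, plus a single absorbing Dead
state shared by both arms.  Cycles are one year; each state is further stratified by
single year of age and sex.

Depression is a prevalence-weighted substate refreshed each cycle (it carries a utility
decrement but, by assumption, no excess mortality), so the fast simulator propagates
occupancy on the (sex, age, BMI, disease) grid and expands to the depression substates
only where utilities and reporting need them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .estimation import DomainError, _band_of
from .synthetic_ehr import BMI_CATEGORIES, EVENT_TYPES, STATE_CLASSES

ARMS: tuple[str, str] = ("surgery", "no_surgery")
N_STATES = 101
DEAD_INDEX = 100
MODEL_AGE_MIN, MODEL_AGE_MAX = 20, 100  # exit after the age-100 cycle
N_AGES = MODEL_AGE_MAX - MODEL_AGE_MIN + 1  # occupancy ages 20..100


@dataclass(frozen=True)
class ModelState:
    """One Markov state; ``dead`` states carry no other attributes."""

    arm: str | None
    bmi_category: str | None
    disease: str | None
    depressed: bool | None
    dead: bool = False

    def __str__(self) -> str:
        if self.dead:
            return "Dead"
        dep = "depressed" if self.depressed else "not-depressed"
        return f"{self.arm}/{self.bmi_category}/{self.disease}/{dep}"


def build_state_space() -> tuple[ModelState, ...]:
    """The 101 model states in stable order: (arm, BMI, disease, depression) with
    Dead last.  2 x 5 x 5 x 2 + 1 = 101."""
    states = [
        ModelState(arm, b, d, dep)
        for arm in ARMS
        for b in BMI_CATEGORIES
        for d in STATE_CLASSES
        for dep in (False, True)
    ]
    states.append(ModelState(None, None, None, None, dead=True))
    return tuple(states)


def state_index(arm: str, bmi_index: int, disease_index: int, depressed: bool) -> int:
    """Index of a live state in the ``build_state_space`` ordering."""
    a = ARMS.index(arm)
    return ((a * 5 + bmi_index) * 5 + disease_index) * 2 + int(depressed)


@dataclass(frozen=True)
class UtilityTable:
    """Utilities: an age curve (same for men and women) minus additive decrements.

    The default age curve is the sex-averaged EQ-5D population-norm quadratic
    u(a) = 0.96146 - 0.0002587 a - 0.0000332 a^2; decrements are negative numbers.
    """

    base_by_age: np.ndarray  # ages 20..100 inclusive (81 values)
    disease_decrements: Mapping[str, float]
    depression_decrement: float
    bmi_decrements: tuple[float, float, float, float, float]
    effective_sample_size: float = 500.0  # beta-PSA concentration

    def __post_init__(self):
        if len(self.base_by_age) != 81:
            raise ValueError("base_by_age must cover ages 20..100 (81 values)")
        if any(d > 0 for d in self.bmi_decrements) or self.depression_decrement > 0:
            raise ValueError("decrements must be <= 0")

    def base(self, age) -> np.ndarray | float:
        a = np.clip(np.asarray(age, dtype=float), MODEL_AGE_MIN, MODEL_AGE_MAX)
        val = np.interp(a, np.arange(MODEL_AGE_MIN, MODEL_AGE_MAX + 1), self.base_by_age)
        return float(val) if np.isscalar(age) else val


def default_utility_table() -> UtilityTable:
    ages = np.arange(MODEL_AGE_MIN, MODEL_AGE_MAX + 1, dtype=float)
    base = 0.9614629 - 0.0002587 * ages - 0.0000332 * ages**2
    return UtilityTable(
        base_by_age=base,
        disease_decrements={"at_risk": 0.0, "diabetes": -0.07, "chd": -0.09,
                            "stroke": -0.16, "cancer": -0.15},
        depression_decrement=-0.12,
        bmi_decrements=(0.0, 0.0, -0.085, -0.17, -0.255),
    )


def surgery_utility_benefit(table: UtilityTable) -> float:
    """Magnitude of a two-BMI-category utility step (the post-surgical benefit)."""
    return abs(table.bmi_decrements[4] - table.bmi_decrements[2])


@dataclass(frozen=True)
class InterventionSpec:
    """Effects and costs of bariatric surgery.  Relative risks are (point, lo, hi)
    with 95% intervals; cancer incidence reduction applies to women only."""

    rr_incidence: Mapping[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "diabetes": (0.20, 0.13, 0.30),
        "chd": (0.67, 0.54, 0.83),
        "stroke": (0.67, 0.54, 0.83),
        "cancer": (0.58, 0.44, 0.77),
    })
    cancer_women_only: bool = True
    rr_mortality: tuple[float, float, float] = (0.45, 0.36, 0.56)
    rr_depression: Mapping[int, tuple[float, float, float]] = field(default_factory=lambda: {
        1: (0.82, 0.78, 0.87), 2: (0.83, 0.76, 0.90), 3: (0.87, 0.78, 0.97),
    })
    diabetes_remission: float = 0.40
    operative_mortality: float = 0.0007
    reoperation_rate: float = 0.02  # per year
    reoperation_cost: float = 3620.0
    cost_preop: float = 1024.0
    cost_procedure: float = 7015.0
    cost_postop_review: float = 875.0
    cost_leaks: float = 250.0
    tariffs: tuple[float, float, float] = (3620.0, 8713.0, 8713.0)  # LAGB, bypass, sleeve
    procedure_cost_multiplier: float = 1.0
    utility_benefit_scale: float = 1.0  # 0 disables the post-surgical utility gain
    utility_benefit_decay_exponent: float = -0.25
    effect_decay_exponent: float | None = None  # global RR decay (None, -0.25, -0.50)

    def __post_init__(self):
        for name, (rr, lo, hi) in self.rr_incidence.items():
            if not (0 < lo <= rr <= hi):
                raise ValueError(f"invalid RR interval for {name}")
        if not 0.0 <= self.diabetes_remission <= 1.0:
            raise ValueError("diabetes_remission must lie in [0, 1]")

    @property
    def total_procedure_cost(self) -> float:
        """Sum of the cost components (base case: 1024 + 7015 + 875 + 250 = 9164)."""
        return self.cost_preop + self.cost_procedure + self.cost_postop_review + self.cost_leaks

    @property
    def procedure_cost(self) -> float:
        return self.procedure_cost_multiplier * self.total_procedure_cost

    @property
    def tariff_average(self) -> float:
        return sum(self.tariffs) / len(self.tariffs)

    @property
    def expected_reoperation_cost(self) -> float:
        """Expected annual re-operation cost per post-operative person-year."""
        return self.reoperation_rate * self.reoperation_cost

    def depression_rr(self, post_op_year: int) -> float:
        """Depression-prevalence RR; the last tabulated year is carried forward."""
        years = sorted(self.rr_depression)
        y = min(post_op_year, years[-1])
        return self.rr_depression[y][0] if y in self.rr_depression else 1.0

    @classmethod
    def null(cls) -> "InterventionSpec":
        """An intervention with no effects and no costs (arm-equivalence checks)."""
        return cls(
            rr_incidence={k: (1.0, 1.0, 1.0) for k in EVENT_TYPES},
            rr_mortality=(1.0, 1.0, 1.0),
            rr_depression={1: (1.0, 1.0, 1.0)},
            diabetes_remission=0.0, operative_mortality=0.0,
            reoperation_rate=0.0, cost_preop=0.0, cost_procedure=0.0,
            cost_postop_review=0.0, cost_leaks=0.0, utility_benefit_scale=0.0,
        )


def decay_multiplier(post_op_year: float, exponent: float) -> float:
    """Time decay of the intervention effect: year ** exponent (year >= 1)."""
    if post_op_year < 1:
        raise DomainError(f"post-operative year must be >= 1, got {post_op_year}")
    return float(post_op_year) ** exponent


def effective_rr(rr: float, post_op_year: int, exponent: float | None) -> float:
    """RR attenuated toward 1 by the decay factor: 1 - (1 - rr) * year**exponent."""
    if exponent is None:
        return rr
    return 1.0 - (1.0 - rr) * decay_multiplier(post_op_year, exponent)


@dataclass(frozen=True)
class InitialPopulationSpec:
    """Composition of the population entering the model (base case: 200,000 morbidly
    obese adults, half men, mean age 46 over 20-74; 77% no morbidity, 19% diabetes,
    4% CHD)."""

    total: int = 200_000
    n_men: int = 100_000
    n_women: int = 100_000
    age_range: tuple[int, int] = (20, 74)
    age_mean: float = 46.0
    age_sd: float = 13.0
    disease_counts: Mapping[str, int] = field(default_factory=lambda: {
        "at_risk": 153_846, "diabetes": 38_462, "chd": 7_692,
    })
    bmi_category: str = ">=40"

    def __post_init__(self):
        if self.n_men + self.n_women != self.total:
            raise ValueError("sex counts must sum to total")
        if sum(self.disease_counts.values()) != self.total:
            raise ValueError("disease counts must sum to total")
        lo, hi = self.age_range
        if not (MODEL_AGE_MIN <= lo < hi < MODEL_AGE_MAX):
            raise ValueError("age_range must lie within [20, 100)")


def _entry_age_pmf(spec: InitialPopulationSpec) -> np.ndarray:
    """Truncated-normal pmf over integer entry ages (the exact register age
    distribution is not published; mean/range are matched)."""
    lo, hi = spec.age_range
    ages = np.arange(lo, hi + 1, dtype=float)
    dens = np.exp(-0.5 * ((ages - spec.age_mean) / spec.age_sd) ** 2)
    return dens / dens.sum()


def build_initial_population(spec: InitialPopulationSpec) -> np.ndarray:
    """Occupancy array (sex 2, age 81: 20..100, bmi 5, disease 5) summing to
    ``spec.total``.

    Mass is apportioned continuously (no integer rounding), so marginal totals match
    the configured counts exactly.
    """
    occ = np.zeros((2, N_AGES, 5, 5))
    if spec.total == 0:
        return occ
    pmf = _entry_age_pmf(spec)
    lo, _ = spec.age_range
    b = BMI_CATEGORIES.index(spec.bmi_category)
    sex_counts = {0: spec.n_women, 1: spec.n_men}
    for cls, count in spec.disease_counts.items():
        d = STATE_CLASSES.index(cls)
        frac = count / spec.total
        for s, n_s in sex_counts.items():
            occ[s, lo - MODEL_AGE_MIN: lo - MODEL_AGE_MIN + len(pmf), b, d] += n_s * frac * pmf
    return occ


def baseline_transition_row(state: ModelState, age: int, sex: int, psa_draw,
                            depression_prev: np.ndarray | None = None,
                            bmi_transition: np.ndarray | None = None) -> np.ndarray:
    """One-cycle transition probabilities out of ``state`` as a row over the 101
    states.  Competing risks resolve in a fixed order: death first, then disease
    incidence among survivors (from at-risk only), then BMI-category movement.
    Diseases are mutually exclusive and absorbing; Dead is absorbing.
    """
    row = np.zeros(N_STATES)
    if state.dead:
        row[DEAD_INDEX] = 1.0
        return row
    if not MODEL_AGE_MIN <= age <= 99:
        raise DomainError(f"age outside model range [20, 99]: {age}")
    ai = age - MODEL_AGE_MIN
    b = BMI_CATEGORIES.index(state.bmi_category)
    d = STATE_CLASSES.index(state.disease)
    p_death = float(psa_draw.p_death[ai, sex, b, d])
    row[DEAD_INDEX] = p_death
    surv = 1.0 - p_death
    bmi_row = np.eye(5)[b] if bmi_transition is None else bmi_transition[b]

    def put(disease_idx: int, mass: float) -> None:
        for b2 in range(5):
            if bmi_row[b2]:
                row[state_index(state.arm, b2, disease_idx, state.depressed)] += mass * bmi_row[b2]

    if d == 0:
        p_inc = np.asarray(psa_draw.p_incidence[ai, sex, b], dtype=float).copy()
        total_inc = p_inc.sum()
        if total_inc > 1.0:  # competing incidences overflow; renormalise and log
            import logging
            logging.getLogger(__name__).warning(
                "incidence probabilities sum to %.3f > 1 at age %d; renormalising", total_inc, age)
            p_inc /= total_inc
            total_inc = 1.0
        for k in range(4):
            put(k + 1, surv * p_inc[k])
        put(0, surv * (1.0 - total_inc))
    else:
        put(d, surv)
    return row


def apply_intervention(row: np.ndarray, state: ModelState, spec: InterventionSpec,
                       post_op_year: int, sex: int = 0) -> np.ndarray:
    """Scale the incidence and death probabilities of a surgery-arm row by the
    intervention relative risks; the freed probability mass goes to the stay state.
    The cancer RR applies to women only."""
    if state.dead:
        return row.copy()
    if post_op_year < 1:
        raise DomainError("post_op_year must be >= 1")
    out = row.copy()
    d = STATE_CLASSES.index(state.disease)
    b = BMI_CATEGORIES.index(state.bmi_category)
    stay = state_index(state.arm, b, d, state.depressed)
    freed = 0.0
    rr_m = effective_rr(spec.rr_mortality[0], post_op_year, spec.effect_decay_exponent)
    freed += out[DEAD_INDEX] * (1.0 - rr_m)
    out[DEAD_INDEX] *= rr_m
    if d == 0:
        for k, ev in enumerate(EVENT_TYPES):
            if ev == "cancer" and spec.cancer_women_only and sex == 1:
                continue
            rr = effective_rr(spec.rr_incidence[ev][0], post_op_year,
                              spec.effect_decay_exponent)
            for b2 in range(5):
                j = state_index(state.arm, b2, k + 1, state.depressed)
                freed += out[j] * (1.0 - rr)
                out[j] *= rr
    out[stay] += freed
    if not -1e-12 <= out[stay] <= 1 + 1e-12:
        raise ValueError("adjusted stay probability outside [0, 1]")
    return out


def apply_remission_and_operative_mortality(
    occupancy: np.ndarray, spec: InterventionSpec
) -> tuple[np.ndarray, float]:
    """Cycle-0 surgery-arm adjustments: move ``diabetes_remission`` of the diabetes
    occupancy to at-risk (same stratum), then remove ``operative_mortality`` of all
    entrants to Dead.  Returns (adjusted occupancy, operative deaths)."""
    occ = occupancy.copy()
    moved = spec.diabetes_remission * occ[..., 1]
    occ[..., 1] -= moved
    occ[..., 0] += moved
    deaths = spec.operative_mortality * occ.sum()
    occ *= 1.0 - spec.operative_mortality
    return occ, float(deaths)


def state_utility(state: ModelState, age: float, table: UtilityTable,
                  post_op_year: int | None = None,
                  utility_shift: Mapping[str, float] | None = None,
                  spec: InterventionSpec | None = None) -> float:
    """Utility of one state at one age: age curve + disease + depression + BMI
    decrements, plus the decaying post-surgical benefit in the surgery arm;
    clamped at 1."""
    if state.dead:
        return 0.0
    u = table.base(age)
    u += table.disease_decrements.get(state.disease, 0.0)
    if state.depressed:
        u += table.depression_decrement
    u += table.bmi_decrements[BMI_CATEGORIES.index(state.bmi_category)]
    if utility_shift is not None:
        u += utility_shift.get(state.disease, 0.0)
    if state.arm == "surgery" and post_op_year is not None:
        s = spec or InterventionSpec()
        benefit = s.utility_benefit_scale * surgery_utility_benefit(table)
        u += benefit * decay_multiplier(post_op_year, s.utility_benefit_decay_exponent)
    return float(min(u, 1.0))


def state_cost(state: ModelState, age: float, sex: int, cost_means: np.ndarray,
               post_op_year: int | None = None,
               spec: InterventionSpec | None = None) -> float:
    """Annual cost of one state: utilization cost by (disease, age band, sex) —
    identical in both arms — plus, in the surgery arm, the procedure cost in the
    first post-operative year and the expected re-operation cost thereafter."""
    if state.dead:
        return 0.0
    d = STATE_CLASSES.index(state.disease)
    c = float(cost_means[d, int(_band_of(age)), sex])
    if c < 0:
        raise ValueError("negative cost draw")
    if state.arm == "surgery" and post_op_year is not None:
        s = spec or InterventionSpec()
        if post_op_year == 1:
            c += s.procedure_cost
        else:
            c += s.expected_reoperation_cost
    return c
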