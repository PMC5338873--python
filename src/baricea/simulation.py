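"""Probabilistic cohort simulation: PSA parameter draws and 81-cycle cohort traces.

Each probabilistic-sensitivity-analysis (PSA) draw samples transition probabilities
from beta distributions parameterised by the evidence counts (beta-binomial), state
costs from gamma distributions around the two-part means, state utilities and
depression prevalences from beta distributions, and intervention relative risks from
lognormals matched to their published 95% intervals.  A paired cohort run (surgery vs
no surgery) then propagates the 200,000-person initial population through the model,
ageing one year per cycle, with exit at age 100, accumulating discounted costs and
QALYs at 0%, 1.5% and 3.5% simultaneously.

Common random numbers are used across arms by default (one parameter draw shared by
both arms of a pair), which makes the incremental outcomes of a null intervention
exactly zero and sharpens the percentile intervals of the incrementals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimation import AGE_BANDS, ModelParameters, TransitionEvidenceTable, _band_of
from .model_core import (
    MODEL_AGE_MIN,
    N_AGES,
    InitialPopulationSpec,
    InterventionSpec,
    UtilityTable,
    apply_remission_and_operative_mortality,
    build_initial_population,
    decay_multiplier,
    default_utility_table,
    surgery_utility_benefit,
)
from .synthetic_ehr import EVENT_TYPES, STATE_CLASSES

DISCOUNT_RATES: tuple[float, ...] = (0.0, 0.015, 0.035)
N_CYCLES = 81


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor (1 + rate)**(-cycle); cycle 0 (the procedure year) is
    undiscounted."""
    return (1.0 + rate) ** (-cycle)


@dataclass
class PSADraw:
    """One sampled parameter set.  Transition arrays are indexed
    [age(80), sex(2), bmi(5), destination]."""

    seed: int | None
    p_incidence: np.ndarray          # (80, 2, 5, 4)
    p_death: np.ndarray              # (80, 2, 5, 5)
    cost_means: np.ndarray           # (5 classes, 4 age bands, 2 sexes), GBP/year
    depression_prev: np.ndarray      # (5,)
    utility_shift: np.ndarray        # (5,) additive class-level utility perturbation
    rr_incidence: dict[str, float]
    rr_mortality: float
    rr_depression: dict[int, float]


def _beta_binomial(rng: np.random.Generator, r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Beta(r, n - r) draws with a +1/2 continuity correction at the boundaries."""
    a = r.copy()
    b = n - r
    edge = (a <= 0) | (b <= 0)
    a = np.where(edge, a + 0.5, a)
    b = np.where(edge, b + 0.5, b)
    return rng.beta(a, b)


def _lognormal_rr(rng: np.random.Generator, interval: tuple[float, float, float]) -> float:
    point, lo, hi = interval
    if lo == hi == point:
        return point
    sd = (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
    return float(np.exp(rng.normal(np.log(point), sd)))


def sample_psa_draw(
    evidence: TransitionEvidenceTable,
    intervention_spec: InterventionSpec,
    utility_table: UtilityTable,
    seed,
    depression: np.ndarray | None = None,
    depression_counts: Sequence[tuple[int, int]] | None = None,
    cost_means: np.ndarray | None = None,
    cost_n: np.ndarray | None = None,
    sample_effects: bool = True,
    point_estimate: bool = False,
) -> PSADraw:
    """Sample one PSA parameter set; reproducible under ``seed``.

    With ``point_estimate`` the evidence means are used unsampled (deterministic run).
    """
    rng = np.random.default_rng(seed)
    if point_estimate:
        p_inc = evidence.p_incidence.copy()
        p_death = evidence.p_death.copy()
    else:
        p_inc = _beta_binomial(rng, evidence.r_incidence,
                               np.broadcast_to(evidence.n_at_risk[..., None],
                                               evidence.p_incidence.shape))
        p_death = _beta_binomial(rng, evidence.r_death, evidence.n_by_class)

    if cost_means is None:
        cost_means = np.zeros((5, len(AGE_BANDS), 2))
        cost_n = np.ones_like(cost_means)
    if point_estimate:
        cm = cost_means.copy()
    else:
        n = np.maximum(np.asarray(cost_n, dtype=float), 1.0)
        cm = np.where(cost_means > 0, rng.gamma(n, np.maximum(cost_means, 1e-12) / n), 0.0)

    if depression is None:
        depression = np.zeros(5)
    dep = np.asarray(depression, dtype=float).copy()
    if not point_estimate and depression_counts is not None:
        num = np.array([c[0] for c in depression_counts], dtype=float)
        den = np.array([c[1] for c in depression_counts], dtype=float)
        dep = _beta_binomial(rng, num, den)

    shift = np.zeros(5)
    if not point_estimate:
        ess = utility_table.effective_sample_size
        ref = utility_table.base(60.0)
        for c, cls in enumerate(STATE_CLASSES):
            m = float(np.clip(ref + utility_table.disease_decrements.get(cls, 0.0), 0.01, 0.99))
            shift[c] = rng.beta(m * ess, (1 - m) * ess) - m

    if sample_effects and not point_estimate:
        rr_inc = {k: _lognormal_rr(rng, v) for k, v in intervention_spec.rr_incidence.items()}
        rr_mort = _lognormal_rr(rng, intervention_spec.rr_mortality)
        rr_dep = {y: _lognormal_rr(rng, v) for y, v in intervention_spec.rr_depression.items()}
    else:
        rr_inc = {k: v[0] for k, v in intervention_spec.rr_incidence.items()}
        rr_mort = intervention_spec.rr_mortality[0]
        rr_dep = {y: v[0] for y, v in intervention_spec.rr_depression.items()}

    return PSADraw(
        seed=None if not np.isscalar(seed) else int(seed),
        p_incidence=p_inc, p_death=p_death, cost_means=cm, depression_prev=dep,
        utility_shift=shift, rr_incidence=rr_inc, rr_mortality=rr_mort,
        rr_depression=rr_dep,
    )


@dataclass
class CohortTrace:
    """Result of one arm's cohort run."""

    arm: str
    entrants: float
    occupancy: np.ndarray        # (n_cycles + 1, 2, 80, 5, 5)
    dead: float
    exited_at_100: float
    costs: dict[float, float]    # discount rate -> total GBP
    qalys: dict[float, float]
    person_years: np.ndarray     # (5,) by disease class
    depression_person_years: float
    life_years: float


def _depression_rr_for_year(draw: PSADraw, post_op_year: int) -> float:
    if not draw.rr_depression:
        return 1.0
    years = sorted(draw.rr_depression)
    return draw.rr_depression[min(post_op_year, years[-1])]


def run_cohort(
    arm: str,
    draw: PSADraw,
    initial_occupancy: np.ndarray,
    intervention_spec: InterventionSpec | None = None,
    utility_table: UtilityTable | None = None,
    n_cycles: int = N_CYCLES,
    discount_rates: Sequence[float] = DISCOUNT_RATES,
    bmi_transition: np.ndarray | None = None,
    track_history: bool = False,
    conservation_tol: float = 1e-6,
) -> CohortTrace:
    """Propagate an initial occupancy through ``n_cycles`` annual cycles.

    Within a cycle: costs and QALYs accrue to the cycle-start occupancy (no half-cycle
    correction), then death is resolved, then disease incidence among survivors, then
    BMI movement, then everyone ages one year (exit at 100).  Mass conservation
    (live + dead + exited = entrants) is asserted each cycle.
    """
    spec = intervention_spec or InterventionSpec()
    table = utility_table or default_utility_table()
    surgery = arm == "surgery"
    occ = np.asarray(initial_occupancy, dtype=float).copy()
    entrants = float(occ.sum())
    dead = 0.0
    exited = 0.0
    costs = {r: 0.0 for r in discount_rates}
    qalys = {r: 0.0 for r in discount_rates}
    person_years = np.zeros(5)
    dep_py = 0.0
    life_years = 0.0
    history = [occ.copy()] if track_history else None

    ages = np.arange(MODEL_AGE_MIN, MODEL_AGE_MIN + N_AGES, dtype=float)  # 20..100
    bands = _band_of(ages)  # (81,)
    base_u = table.base(ages)  # (81,)
    dis_dec = np.array([table.disease_decrements.get(c, 0.0) for c in STATE_CLASSES])
    bmi_dec = np.asarray(table.bmi_decrements)
    benefit = spec.utility_benefit_scale * surgery_utility_benefit(table)

    # (2, 80, 5cls) utilisation cost per person-year; identical across arms.
    cmat = draw.cost_means[:, bands, :]            # (5, 80, 2)
    cmat = np.transpose(cmat, (2, 1, 0))           # (2, 80, 5)
    p_death = np.moveaxis(draw.p_death, 0, 1)      # (2, 80, 5, 5)
    p_inc = np.moveaxis(draw.p_incidence, 0, 1)    # (2, 80, 5, 4)

    for cycle in range(n_cycles):
        post_op_year = cycle + 1
        if cycle == 0 and surgery:
            occ, op_deaths = apply_remission_and_operative_mortality(occ, spec)
            dead += op_deaths

        alive = occ.sum()
        # --- accrual at cycle start ---
        dep_prev = draw.depression_prev.copy()
        if surgery:
            dep_prev = np.clip(dep_prev * _depression_rr_for_year(draw, post_op_year), 0.0, 1.0)
        # utilities of the not-depressed / depressed substates, clamped at 1
        u = (base_u[None, :, None, None] + bmi_dec[None, None, :, None]
             + dis_dec[None, None, None, :] + draw.utility_shift[None, None, None, :])
        if surgery:
            u = u + benefit * decay_multiplier(post_op_year, spec.utility_benefit_decay_exponent)
        u_nodep = np.minimum(u, 1.0)
        u_dep = np.minimum(u + table.depression_decrement, 1.0)
        u_eff = (1.0 - dep_prev) * u_nodep + dep_prev * u_dep

        cost_cycle = float(np.einsum("sabd,sad->", occ, cmat))
        if surgery:
            if cycle == 0:
                cost_cycle += spec.procedure_cost * entrants
            else:
                cost_cycle += spec.expected_reoperation_cost * alive
        qaly_cycle = float((occ * u_eff).sum())
        for r in discount_rates:
            df = discount_factor(r, cycle)
            costs[r] += df * cost_cycle
            qalys[r] += df * qaly_cycle
        by_class = occ.sum(axis=(0, 1, 2))
        person_years += by_class
        dep_py += float((by_class * dep_prev).sum())
        life_years += alive

        # --- transitions: death, then incidence among survivors, then BMI moves ---
        pd_eff = p_death
        pi_eff = p_inc
        if surgery:
            decay = (decay_multiplier(post_op_year, spec.effect_decay_exponent)
                     if spec.effect_decay_exponent is not None else 1.0)
            rr_m = 1.0 - (1.0 - draw.rr_mortality) * decay
            pd_eff = p_death * rr_m
            rr_vec = 1.0 - (1.0 - np.array([draw.rr_incidence[e] for e in EVENT_TYPES])) * decay
            pi = p_inc * rr_vec[None, None, None, :]
            if spec.cancer_women_only:
                pi[1, ..., 3] = p_inc[1, ..., 3]  # men keep baseline cancer incidence
            pi_eff = pi

        # Transitions apply to ages 20..99; the age-100 slot exits after accrual.
        occ_t = occ[:, :-1]
        exited += float(occ[:, -1].sum())
        dead_new = float((occ_t * pd_eff).sum())
        survivors = occ_t * (1.0 - pd_eff)
        at_risk = survivors[..., 0]
        total_inc = pi_eff.sum(axis=-1)
        scale = np.where(total_inc > 1.0, 1.0 / np.maximum(total_inc, 1e-300), 1.0)
        pi_use = pi_eff * scale[..., None]
        new_occ = survivors.copy()
        new_occ[..., 0] = at_risk * (1.0 - np.minimum(total_inc, 1.0))
        new_occ[..., 1:] += at_risk[..., None] * pi_use
        if bmi_transition is not None:
            new_occ = np.einsum("sabd,bB->saBd", new_occ, bmi_transition)

        aged = np.zeros_like(occ)
        aged[:, 1:] = new_occ
        occ = aged
        dead += dead_new

        total = occ.sum() + dead + exited
        if abs(total - entrants) > conservation_tol:
            raise RuntimeError(
                f"mass conservation violated at cycle {cycle}: {total!r} vs {entrants!r}")
        if track_history:
            history.append(occ.copy())

    occupancy = np.stack(history) if track_history else occ[None]
    return CohortTrace(arm=arm, entrants=entrants, occupancy=occupancy, dead=dead,
                       exited_at_100=exited, costs=costs, qalys=qalys,
                       person_years=person_years, depression_person_years=dep_py,
                       life_years=life_years)


@dataclass
class PairedRun:
    """One PSA draw's paired (surgery, no-surgery) outcome."""

    seed: int | None
    surgery: CohortTrace
    comparator: CohortTrace

    def incremental_cost(self, rate: float) -> float:
        return self.surgery.costs[rate] - self.comparator.costs[rate]

    def incremental_qalys(self, rate: float) -> float:
        return self.surgery.qalys[rate] - self.comparator.qalys[rate]


@dataclass
class SimulationConfig:
    """Everything needed to run a paired PSA."""

    params: ModelParameters
    initial_spec: InitialPopulationSpec = field(default_factory=InitialPopulationSpec)
    intervention: InterventionSpec = field(default_factory=InterventionSpec)
    utility_table: UtilityTable = field(default_factory=default_utility_table)
    discount_rates: tuple[float, ...] = DISCOUNT_RATES
    n_cycles: int = N_CYCLES
    bmi_transition: np.ndarray | None = None
    common_random_numbers: bool = True
    sample_effects: bool = True


def run_psa(n_sims: int, base_seed: int, config: SimulationConfig,
            progress: bool = False) -> list[PairedRun]:
    """Run ``n_sims`` paired cohort simulations with per-draw parameter sampling."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    params = config.params
    initial = build_initial_population(config.initial_spec)
    dep_counts = [(params.depression[c].numerator, params.depression[c].denominator)
                  for c in STATE_CLASSES]
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(2 * n_sims)
    results = []
    for i in range(n_sims):
        s_a, s_b = children[2 * i], children[2 * i + 1]
        draw = sample_psa_draw(
            params.evidence, config.intervention, config.utility_table, s_a,
            depression=params.depression_prevalence_array(),
            depression_counts=dep_counts,
            cost_means=params.cost_mean_array(), cost_n=params.cost_n_array(),
            sample_effects=config.sample_effects)
        if config.common_random_numbers:
            draw_b = draw
        else:
            draw_b = sample_psa_draw(
                params.evidence, config.intervention, config.utility_table, s_b,
                depression=params.depression_prevalence_array(),
                depression_counts=dep_counts,
                cost_means=params.cost_mean_array(), cost_n=params.cost_n_array(),
                sample_effects=config.sample_effects)
        kwargs = dict(n_cycles=config.n_cycles, discount_rates=config.discount_rates,
                      bmi_transition=config.bmi_transition)
        surgery = run_cohort("surgery", draw, initial, config.intervention,
                             config.utility_table, **kwargs)
        comparator = run_cohort("no_surgery", draw_b, initial, config.intervention,
                                config.utility_table, **kwargs)
        results.append(PairedRun(seed=i, surgery=surgery, comparator=comparator))
        if progress and (i + 1) % 10 == 0:
            import logging
            logging.getLogger(__name__).info("PSA draw %d/%d complete", i + 1, n_sims)
    return results
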