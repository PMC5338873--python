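"""Estimation of decision-model inputs from a (synthetic) EHR cohort.

Four estimators feed the Markov model:

* Weibull proportional-hazards fits for the incidence of each comorbidity (censoring at
  the first comorbidity of *any* type, death or record end) and for mortality (records
  split into pre-/post-onset episodes so comorbidity enters as an indicator covariate);
  both left-truncated at the entry age.
* Annual transition probabilities p(a) = 1 - exp(-[H(a+1) - H(a)]) from the fitted
  cumulative hazard, tabulated into per-stratum event/exposure evidence for
  beta-binomial PSA sampling.
* Depression prevalence per model state class, with counts retained for beta sampling.
* Two-part annual costs per state class, age band and sex: probability of any cost plus
  a gamma fit to the positive amounts (ML, method-of-moments fallback).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from ._weibull import AGE_ORIGIN, baseline_cum_hazard, log_baseline_hazard
from .synthetic_ehr import (
    BMI_CATEGORIES,
    EVENT_TYPES,
    STATE_CLASSES,
    Cohort,
    WeibullTruth,
)

logger = logging.getLogger(__name__)

MODEL_AGES = np.arange(20, 100)  # single-year transition strata 20..99
AGE_BANDS: tuple[tuple[int, int], ...] = ((20, 39), (40, 59), (60, 79), (80, 100))


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a valid fit."""


class DomainError(ValueError):
    """Raised when an input lies outside the model's supported domain."""


def _band_of(age) -> np.ndarray:
    edges = np.array([b[0] for b in AGE_BANDS[1:]], dtype=float)
    return np.digitize(np.asarray(age, dtype=float), edges)


@dataclass
class WeibullFit:
    """Fitted Weibull PH model for one event type.

    ``beta`` holds [sex, bmi(4)] for incidence fits and [sex, bmi(4), comorbidity(4)]
    for the mortality fit; ``coef_age``/``coef_age_sq`` modulate the baseline hazard on
    the age timescale (see ``_weibull``).
    """

    event_type: str
    shape: float
    log_scale: float
    coef_age: float
    coef_age_sq: float
    beta: np.ndarray
    param_names: tuple[str, ...]
    cov: np.ndarray | None
    n_events: int
    n_exposure: float  # person-years
    converged: bool
    log_likelihood: float

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_scale))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[np.log(self.shape), self.log_scale,
                                self.coef_age, self.coef_age_sq], self.beta])

    @property
    def se(self) -> dict[str, float]:
        if self.cov is None:
            return {}
        return dict(zip(self.param_names, np.sqrt(np.diag(self.cov))))

    def linear_predictor(self, sex, bmi_index, comorbidity_index=None):
        sex = np.asarray(sex)
        bmi_coefs = np.concatenate([[0.0], self.beta[1:5]])
        lp = self.beta[0] * sex + bmi_coefs[np.asarray(bmi_index)]
        if comorbidity_index is not None:
            if len(self.beta) < 9:
                raise DomainError(f"{self.event_type} fit has no comorbidity coefficients")
            com = np.concatenate([[0.0], self.beta[5:9]])
            idx = np.asarray(comorbidity_index) + 1  # -1 encodes "no comorbidity"
            lp = lp + com[idx]
        return lp

    def cumulative_hazard(self, a0, a1, lp=0.0):
        """H(a1) - H(a0) for linear predictor lp (arrays broadcast)."""
        base = baseline_cum_hazard(a0, a1, self.shape, self.sigma,
                                   self.coef_age, self.coef_age_sq)
        return base * np.exp(lp)

    @classmethod
    def from_truth(cls, truth: WeibullTruth, event_type: str) -> "WeibullFit":
        """Wrap generator truth as an (exact) fit — no sampling uncertainty."""
        beta = [truth.coef_sex, *truth.coef_bmi]
        names = ["log_shape", "log_scale", "age", "age_sq", "sex"] + \
                [f"bmi_{c}" for c in BMI_CATEGORIES[1:]]
        if event_type == "death":
            beta += list(truth.coef_comorbidity)
            names += [f"comorb_{e}" for e in EVENT_TYPES]
        return cls(
            event_type=event_type, shape=truth.shape, log_scale=truth.log_scale_intercept,
            coef_age=truth.coef_age, coef_age_sq=truth.coef_age_sq,
            beta=np.asarray(beta, dtype=float), param_names=tuple(names),
            cov=None, n_events=0, n_exposure=0.0, converged=True, log_likelihood=np.nan,
        )


# Weak ridge on the age-modulation terms: log(a - 20), z and z^2 are nearly collinear
# over a typical entry-age span, so the Weibull power law and the log-quadratic age
# terms can trade off along a likelihood ridge.  The penalty (a N(0, ~0.7) prior on
# each term) pins the ridge near the minimal-modulation parameterisation without
# materially biasing identified directions.
_AGE_RIDGE = 1.0


def _neg_loglik(params: np.ndarray, entry, exit_, delta, X) -> float:
    log_shape, log_scale, ca, caq = params[:4]
    shape, sigma = np.exp(log_shape), np.exp(log_scale)
    lp = X @ params[4:]
    H = baseline_cum_hazard(entry, exit_, shape, sigma, ca, caq, n_nodes=16) * np.exp(lp)
    log_h = log_baseline_hazard(exit_, shape, sigma, ca, caq) + lp
    ll = np.sum(delta * log_h) - np.sum(H) - _AGE_RIDGE * (ca * ca + caq * caq)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _fit_weibull(entry, exit_, delta, X, event_type: str,
                 param_names: Sequence[str]) -> WeibullFit:
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    delta = np.asarray(delta, dtype=float)
    X = np.asarray(X, dtype=float)
    n_events = int(delta.sum())
    if n_events == 0:
        raise EstimationError(f"no {event_type} events in cohort; cannot fit")
    if n_events < 2:
        raise EstimationError(f"fewer than 2 {event_type} events; cannot fit")
    exposure = float(np.sum(exit_ - entry))
    if not exposure > 0:
        raise EstimationError(f"non-positive exposure for {event_type}")

    x0 = np.zeros(4 + X.shape[1])
    x0[1] = np.log(max(exposure / n_events, 1e-3))
    args = (entry, exit_, delta, X)
    # Shape and age-modulation bounds keep the hazard within the family the model is
    # meant to represent (annual hazards graded smoothly in age) and keep the
    # cumulative-hazard quadrature in its accurate regime.
    bounds = [(-2.0, 2.0), (-5.0, 20.0), (-2.0, 2.0), (-1.0, 1.0)] + \
             [(-20.0, 20.0)] * X.shape[1]
    # Stage 1: age modulation frozen (well identified); stage 2: released from there.
    # log(a - 20), z and z^2 are nearly collinear over a typical entry-age span, so
    # the full model sits on a likelihood ridge; a good start keeps L-BFGS-B on it.
    b1 = list(bounds)
    b1[2] = b1[3] = (0.0, 0.0)
    res1 = optimize.minimize(_neg_loglik, x0, args=args, method="L-BFGS-B",
                             bounds=b1, options={"maxiter": 300})
    res = optimize.minimize(_neg_loglik, res1.x, args=args, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": 1000})
    if res1.fun < res.fun:
        res = res1
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn(f"Weibull fit for {event_type} did not converge: {res.message}",
                      RuntimeWarning, stacklevel=2)
    p = res.x
    cov = None
    try:
        hess = numdiff.approx_hess(p, _neg_loglik, args=args)
        # The baseline-vs-age-covariate ridge leaves the Hessian ill conditioned;
        # floor its spectrum so flat directions get (honestly huge) variances.
        w, v = np.linalg.eigh(0.5 * (hess + hess.T))
        w = np.maximum(w, max(w.max(), 1.0) * 1e-8)
        cov = (v / w) @ v.T
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    return WeibullFit(
        event_type=event_type, shape=float(np.exp(p[0])), log_scale=float(p[1]),
        coef_age=float(p[2]), coef_age_sq=float(p[3]), beta=p[4:].copy(),
        param_names=tuple(param_names), cov=cov, n_events=n_events,
        n_exposure=exposure, converged=converged, log_likelihood=float(-res.fun),
    )


def _bmi_index(persons: pd.DataFrame) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(BMI_CATEGORIES)}
    return persons["bmi_category"].map(lookup).to_numpy(dtype=int)


def _incidence_intervals(persons: pd.DataFrame):
    """Analysis interval for incidence: entry to first comorbidity/death/record end."""
    entry = persons["entry_age"].to_numpy(dtype=float)
    exit_ = persons["exit_time"].to_numpy(dtype=float)
    ev = persons["event_time"].to_numpy(dtype=float)
    iexit = np.where(np.isnan(ev), exit_, ev)
    return entry, iexit


_INCIDENCE_PARAMS = ("log_shape", "log_scale", "age", "age_sq", "sex",
                     "bmi_25-29", "bmi_30-34", "bmi_35-39", "bmi_>=40")
_MORTALITY_PARAMS = _INCIDENCE_PARAMS + tuple(f"comorb_{e}" for e in EVENT_TYPES)


def fit_weibull_incidence(cohort: Cohort, event_type: str) -> WeibullFit:
    """ML Weibull PH fit of one comorbidity's incidence (covariates: age, age²
    via the baseline, sex, BMI category); left-truncated, right-censored."""
    if event_type not in EVENT_TYPES:
        raise DomainError(f"unknown event type {event_type!r}")
    persons = cohort.persons
    if len(persons) == 0:
        raise EstimationError(f"no {event_type} events in cohort; cannot fit")
    entry, iexit = _incidence_intervals(persons)
    delta = (persons["event_type"] == event_type).to_numpy()
    keep = iexit > entry
    bmi = _bmi_index(persons)
    sex = persons["sex"].to_numpy(dtype=float)
    X = np.column_stack([sex] + [(bmi == k).astype(float) for k in range(1, 5)])
    return _fit_weibull(entry[keep], iexit[keep], delta[keep], X[keep],
                        event_type, _INCIDENCE_PARAMS)


def fit_weibull_mortality(cohort: Cohort) -> WeibullFit:
    """ML Weibull PH fit of all-cause mortality with comorbidity indicators, splitting
    each record into pre-/post-onset episodes (exact under left truncation)."""
    persons = cohort.persons
    if len(persons) == 0:
        raise EstimationError("no death events in cohort; cannot fit")
    entry = persons["entry_age"].to_numpy(dtype=float)
    exit_ = persons["exit_time"].to_numpy(dtype=float)
    ev = persons["event_time"].to_numpy(dtype=float)
    died = (~persons["death_time"].isna()).to_numpy()
    has_ev = ~np.isnan(ev)
    bmi = _bmi_index(persons)
    sex = persons["sex"].to_numpy(dtype=float)
    ev_idx = pd.Categorical(persons["event_type"], categories=list(EVENT_TYPES)).codes

    # Episode 1: entry to onset (or exit), comorbidity-free.
    e1_end = np.where(has_ev, ev, exit_)
    e1_delta = np.where(has_ev, False, died)
    # Episode 2: onset to exit, comorbid.
    com = np.zeros((len(persons), 4))
    com[has_ev, ev_idx[has_ev]] = 1.0

    entries = np.concatenate([entry, ev[has_ev]])
    exits = np.concatenate([e1_end, exit_[has_ev]])
    deltas = np.concatenate([e1_delta, died[has_ev]])
    X1 = np.column_stack([sex] + [(bmi == k).astype(float) for k in range(1, 5)]
                         + [np.zeros(len(persons))] * 4)
    X2 = np.column_stack([sex[has_ev]] + [(bmi[has_ev] == k).astype(float) for k in range(1, 5)]
                         + [com[has_ev, j] for j in range(4)])
    X = np.vstack([X1, X2])
    keep = exits > entries
    return _fit_weibull(entries[keep], exits[keep], deltas[keep], X[keep],
                        "death", _MORTALITY_PARAMS)


def annual_probability(fit: WeibullFit, covariates: Mapping, age) -> np.ndarray | float:
    """One-year transition probability at ``age``: 1 - exp(-[H(age+1) - H(age)]).

    ``covariates``: ``sex`` (0/1), ``bmi`` (0..4), optional ``comorbidity`` (0..3,
    mortality fit only).  ``age`` must lie in [20, 99]; arrays are supported.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < AGE_ORIGIN) or np.any(a > 99.0):
        raise DomainError(f"age outside model range [20, 99]: {age}")
    lp = fit.linear_predictor(covariates.get("sex", 0), covariates.get("bmi", 0),
                              covariates.get("comorbidity"))
    dH = fit.cumulative_hazard(a, a + 1.0, lp)
    p = 1.0 - np.exp(-dH)
    return float(p) if np.isscalar(age) else p


@dataclass(frozen=True)
class TransitionEvidence:
    """Event count and exposure for one (stratum, destination) pair."""

    age: int
    sex: int
    bmi_index: int
    source_class: str
    destination: str
    r: float
    n: float

    def __post_init__(self):
        if not (0 <= self.r <= self.n and self.n > 0):
            raise ValueError(f"invalid evidence counts r={self.r}, n={self.n}")


@dataclass
class TransitionEvidenceTable:
    """Model-smoothed transition evidence on the full stratum grid.

    Arrays are indexed [age(80: 20..99), sex(2), bmi(5)] plus a destination axis:
    ``p_incidence``/``n_at_risk`` for the four comorbidity destinations from the
    at-risk state, ``p_death``/``n_by_class`` for death from each of the five
    state classes.  ``r = p * n`` per stratum; zero-exposure strata get n = 1
    (maximally diffuse PSA input).
    """

    ages: np.ndarray
    p_incidence: np.ndarray  # (80, 2, 5, 4)
    n_at_risk: np.ndarray    # (80, 2, 5)
    p_death: np.ndarray      # (80, 2, 5, 5) last axis = source class
    n_by_class: np.ndarray   # (80, 2, 5, 5) person-years per source class

    @property
    def r_incidence(self) -> np.ndarray:
        return self.p_incidence * self.n_at_risk[..., None]

    @property
    def r_death(self) -> np.ndarray:
        return self.p_death * self.n_by_class

    def records(self):
        """Flat iterator of TransitionEvidence rows (exhaustive over strata)."""
        for ai, age in enumerate(self.ages):
            for sex in range(2):
                for b in range(5):
                    n0 = self.n_at_risk[ai, sex, b]
                    for k, ev in enumerate(EVENT_TYPES):
                        yield TransitionEvidence(int(age), sex, b, "at_risk", ev,
                                                 float(self.p_incidence[ai, sex, b, k] * n0),
                                                 float(n0))
                    for c, cls in enumerate(STATE_CLASSES):
                        nc = self.n_by_class[ai, sex, b, c]
                        yield TransitionEvidence(int(age), sex, b, cls, "death",
                                                 float(self.p_death[ai, sex, b, c] * nc),
                                                 float(nc))


def _exposure_by_stratum(entry, exit_, sex, bmi) -> np.ndarray:
    """Person-years in each (single-year age, sex, bmi) cell, shape (80, 2, 5)."""
    out = np.zeros((len(MODEL_AGES), 2, 5))
    idx = sex.astype(int) * 5 + bmi
    for ai, a in enumerate(MODEL_AGES):
        contrib = np.clip(np.minimum(exit_, a + 1.0) - np.maximum(entry, float(a)), 0.0, 1.0)
        out[ai] = np.bincount(idx, weights=contrib, minlength=10).reshape(2, 5)
    return out


def build_transition_evidence(cohort: Cohort, fits: Mapping[str, WeibullFit]) -> TransitionEvidenceTable:
    """Tabulate model-smoothed (r, n) evidence over all strata and destinations.

    Probabilities come from the fitted hazards (single-year-of-age raw counts are too
    sparse); effective n is the observed stratum exposure in person-years.
    """
    for name in EVENT_TYPES + ("death",):
        if name not in fits:
            raise EstimationError(f"missing fit for destination {name!r}")
    persons = cohort.persons
    bmi = _bmi_index(persons)
    sex = persons["sex"].to_numpy(dtype=float)
    entry, iexit = _incidence_intervals(persons)
    n_at_risk = _exposure_by_stratum(entry, iexit, sex, bmi)

    ev = persons["event_time"].to_numpy(dtype=float)
    has_ev = ~np.isnan(ev)
    ev_idx = pd.Categorical(persons["event_type"], categories=list(EVENT_TYPES)).codes
    exit_ = persons["exit_time"].to_numpy(dtype=float)
    n_by_class = np.zeros((len(MODEL_AGES), 2, 5, 5))
    n_by_class[..., 0] = n_at_risk
    for k in range(4):
        mask = has_ev & (ev_idx == k)
        if mask.any():
            n_by_class[..., k + 1] = _exposure_by_stratum(
                ev[mask], exit_[mask], sex[mask], bmi[mask])

    zero = int((n_at_risk == 0).sum() + (n_by_class == 0).sum())
    if zero:
        logger.warning("%d empty strata; flooring exposure at 1 person-year "
                       "(maximally diffuse PSA input)", zero)
    n_at_risk = np.maximum(n_at_risk, 1.0)
    n_by_class = np.maximum(n_by_class, 1.0)

    ages_g, sex_g, bmi_g = np.meshgrid(MODEL_AGES.astype(float), np.arange(2),
                                       np.arange(5), indexing="ij")
    p_inc = np.zeros((len(MODEL_AGES), 2, 5, 4))
    for k, name in enumerate(EVENT_TYPES):
        p_inc[..., k] = annual_probability(fits[name], {"sex": sex_g, "bmi": bmi_g}, ages_g)
    p_death = np.zeros((len(MODEL_AGES), 2, 5, 5))
    for c in range(5):
        com = None if c == 0 else np.full_like(bmi_g, c - 1)
        p_death[..., c] = annual_probability(fits["death"],
                                             {"sex": sex_g, "bmi": bmi_g, "comorbidity": com},
                                             ages_g)
    return TransitionEvidenceTable(MODEL_AGES.copy(), p_inc, n_at_risk, p_death, n_by_class)


@dataclass(frozen=True)
class DepressionPrevalence:
    """Depression prevalence in one state class, with beta-sampling counts."""

    state_class: str
    numerator: int
    denominator: int

    def __post_init__(self):
        if self.denominator <= 0:
            raise EstimationError(f"empty state class {self.state_class!r}")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def prevalence(self) -> float:
        return self.numerator / self.denominator


def estimate_depression_prevalence(cohort: Cohort, state_class: str) -> DepressionPrevalence:
    """Exact prevalence of the depression flag among persons in one state class."""
    if state_class not in STATE_CLASSES:
        raise DomainError(f"unknown state class {state_class!r}")
    persons = cohort.persons
    if state_class == "at_risk":
        mask = persons["event_type"] == "none"
    else:
        mask = persons["event_type"] == state_class
    denom = int(mask.sum())
    if denom == 0:
        raise EstimationError(f"no persons in state class {state_class!r}")
    num = int(persons.loc[mask, "depressed"].sum())
    return DepressionPrevalence(state_class, num, denom)


@dataclass
class CostEstimate:
    """Two-part annual-cost estimate for one (state class, age band, sex) cell."""

    state_class: str
    age_band: tuple[int, int] | None
    sex: int | None
    p_any_cost: float
    successes: int
    trials: int
    mean_positive: float  # GBP/year among cost-incurring years
    gamma_shape: float | None
    gamma_scale: float | None
    n_observations: int
    gamma_valid: bool = True

    @property
    def expected_annual_cost(self) -> float:
        return self.p_any_cost * self.mean_positive


def _fit_gamma(pos: np.ndarray) -> tuple[float, float, bool]:
    """(shape, scale, by_ml) for positive costs; MoM fallback on ML failure."""
    mean, var = float(pos.mean()), float(pos.var())
    mom = (mean * mean / var, var / mean) if var > 0 else (1.0, mean)
    if len(pos) < 10 or var == 0:
        return mom[0], mom[1], False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _, scale = stats.gamma.fit(pos, floc=0)
        if np.isfinite(a) and np.isfinite(scale) and a > 0 and scale > 0:
            return float(a), float(scale), True
    except Exception:
        pass
    return mom[0], mom[1], False


def fit_two_part_costs(cohort: Cohort, state_class: str,
                       age_band: tuple[int, int] | None = None,
                       sex: int | None = None) -> CostEstimate:
    """Two-part cost fit over person-years of one state class (optionally one
    age band and sex): P(any cost) from counts, gamma ML on the positive costs."""
    if state_class not in STATE_CLASSES:
        raise DomainError(f"unknown state class {state_class!r}")
    costs = cohort.costs
    mask = costs["state_class"] == state_class
    if age_band is not None or sex is not None:
        p = cohort.persons.set_index("person_id")
        entry = p.loc[costs["person_id"], "entry_age"].to_numpy()
        mid = entry + costs["year_index"].to_numpy() + 0.5
        if age_band is not None:
            mask &= (mid >= age_band[0]) & (mid < age_band[1] + 1)
        if sex is not None:
            mask &= p.loc[costs["person_id"], "sex"].to_numpy() == sex
    vals = costs.loc[mask, "cost"].to_numpy(dtype=float)
    if len(vals) < 10:
        raise EstimationError(
            f"fewer than 10 person-years for costs in {state_class!r} "
            f"(band={age_band}, sex={sex})")
    trials = len(vals)
    pos = vals[vals > 0]
    successes = len(pos)
    if successes == 0:
        return CostEstimate(state_class, age_band, sex, 0.0, 0, trials, 0.0,
                            None, None, trials, gamma_valid=False)
    shape, scale, by_ml = _fit_gamma(pos)
    return CostEstimate(state_class, age_band, sex, successes / trials, successes,
                        trials, float(pos.mean()), shape, scale, trials,
                        gamma_valid=by_ml or len(pos) >= 2)


@dataclass
class ModelParameters:
    """Bundle of everything the simulation needs from the estimation stage."""

    fits: dict[str, WeibullFit]
    evidence: TransitionEvidenceTable
    depression: dict[str, DepressionPrevalence]
    costs: dict[tuple[str, int, int], CostEstimate]  # (class, band index, sex)

    def cost_mean_array(self) -> np.ndarray:
        """Expected annual cost, shape (5 classes, 4 age bands, 2 sexes)."""
        out = np.zeros((5, len(AGE_BANDS), 2))
        for (cls, b, s), est in self.costs.items():
            out[STATE_CLASSES.index(cls), b, s] = est.expected_annual_cost
        return out

    def cost_n_array(self) -> np.ndarray:
        out = np.ones((5, len(AGE_BANDS), 2))
        for (cls, b, s), est in self.costs.items():
            out[STATE_CLASSES.index(cls), b, s] = max(est.n_observations, 1)
        return out

    def depression_prevalence_array(self) -> np.ndarray:
        return np.array([self.depression[c].prevalence for c in STATE_CLASSES])


def estimate_all(cohort: Cohort) -> ModelParameters:
    """Run the full estimation stage on one cohort."""
    fits = {ev: fit_weibull_incidence(cohort, ev) for ev in EVENT_TYPES}
    fits["death"] = fit_weibull_mortality(cohort)
    evidence = build_transition_evidence(cohort, fits)
    depression = {c: estimate_depression_prevalence(cohort, c) for c in STATE_CLASSES}
    costs: dict[tuple[str, int, int], CostEstimate] = {}
    for cls in STATE_CLASSES:
        fallback = fit_two_part_costs(cohort, cls)
        for b in range(len(AGE_BANDS)):
            for s in (0, 1):
                try:
                    costs[(cls, b, s)] = fit_two_part_costs(cohort, cls, AGE_BANDS[b], s)
                except EstimationError:
                    logger.warning("sparse cost cell (%s, band %d, sex %d); "
                                   "using class-level estimate", cls, b, s)
                    costs[(cls, b, s)] = fallback
    return ModelParameters(fits, evidence, depression, costs)
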