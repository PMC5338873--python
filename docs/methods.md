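# Methods

`baricea` implements a probabilistic cost-utility analysis of bariatric surgery versus
standard non-surgical management of obesity, together with the epidemiological
estimation stages that feed it and a synthetic primary-care cohort generator that
stands in for the (non-redistributable) EHR extract such analyses are built on.

## The decision model

**State space.** A Markov cohort model with 101 states: 2 treatment arms x 5 BMI
categories (18.5–25, 25–29, 30–34, 35–39, >=40 kg/m²) x 5 disease states (at risk,
diabetes, CHD, stroke, cancer) x 2 depression substates, plus one absorbing Dead state
shared by both arms. Every state is further stratified by single year of age and sex.
Cycles are one year; the cohort ages one year per cycle, accrues costs and utilities at
cycle start (no half-cycle correction), and exits after the age-100 cycle. An entrant
aged 20 can therefore accrue up to 81 cycle-years (ages 20–100), which fixes the
81-cycle horizon.

**Transitions.** Within a cycle, competing risks resolve in a fixed order: death
first, then disease incidence among survivors (possible only from the at-risk state;
diseases are mutually exclusive and absorbing), then optional BMI-category movement
(identity by default — no published rates accompany the structure, and post-surgical
costs are explicitly not weight-linked, so the base case carries the surgical benefit
entirely in the utility term). Total probability is conserved to 1e-12 per row and
total cohort mass (live + dead + exited) to 1e-6 persons per cycle.

**Depression** is a prevalence-weighted substate refreshed each cycle rather than a
transition with memory: it carries a utility decrement but no excess mortality
(mortality is assumed independent of depression status). The surgery arm multiplies
the prevalence by the post-operative relative risks (0.82 / 0.83 / 0.87 in years 1–3);
the year-3 value is carried forward afterwards, since no later estimates are published.

**Intervention.** Surgery is modelled as (i) relative risks on disease incidence —
diabetes 0.20, CHD 0.67, stroke 0.67, cancer 0.58 (women only) — and on mortality
(0.45); (ii) a one-time cycle-0 redistribution moving 40% of prevalent diabetes to
at-risk (remission; relapse occurs only through the attenuated incidence transition);
(iii) operative mortality of 0.07% at cycle 0; (iv) costs: GBP 9,164 per entrant at
cycle 0 (preoperative management 1,024 + procedure tariff 7,015 + postoperative review
875 + leak costs 250) and an expected re-operation cost of 2%/yr x GBP 3,620 =
GBP 72.40 per subsequent post-operative person-year; (v) a utility benefit equal in
magnitude to a two-BMI-category step (|-0.255 - (-0.085)| = 0.17), decaying as
year^(-0.25). Sensitivity analyses additionally attenuate every relative risk toward 1
by year^e with e in {-0.25, -0.50}: rr(t) = 1 - (1 - rr) t^e, so the *effect* declines
by 44% (68%) over 10 years.

**Utilities.** A single age curve (identical for men and women) minus additive
decrements for disease, depression, and BMI category (0 / 0 / -0.085 / -0.17 / -0.255),
clamped at 1. The default age curve is the sex-averaged EQ-5D population-norm
quadratic u(a) = 0.96146 - 0.0002587 a - 0.0000332 a²; the disease and depression
decrements are package defaults of typical published magnitude, since standard
utility compendia are not redistributable.

**PSA.** Each draw samples transition probabilities from Beta(r, n - r) per
(age, sex, BMI, source-state) stratum — the beta-binomial scheme, with a +1/2
continuity correction at the boundaries; state mean costs from gamma distributions
with CV 1/sqrt(n_obs); depression prevalences from Beta(numerator, denominator);
state-class utilities from beta distributions (one draw per disease class, effective
sample size 500, applied as an additive shift to the age curve — the published
dispersion is unavailable, so this is a package choice); and intervention relative
risks from lognormals matched to the published 95% intervals. Common random numbers
pair the two arms within a draw (switchable): this makes a null intervention's
incrementals exactly zero and sharpens the percentile CIs of the incrementals.
Results are reported per 1,000 entrants, discounted at 0%, 1.5% and 3.5%
simultaneously, with empirical 2.5/97.5 percentile intervals over draws. The ICER is
reported as the ratio of mean incrementals, with the per-draw ratio distribution
retained for its CI; NMB = λΔQ - ΔC and NHB = ΔQ - ΔC/λ at λ = 20,000 and 30,000
GBP/QALY hold per draw by construction.

**Initial population.** 200,000 persons (100,000 per sex) aged 20–74 (truncated-normal
ages, mean 46, SD 13 — the exact register distribution is not published), all in the
configured entry BMI category (base case >= 40), split 77% / 19% / 4% across
no-morbidity / diabetes / CHD. Mass is apportioned continuously, so marginal totals
are exact.

## Survival model and estimation

**Timescale.** All time-to-event machinery lives on the *age* scale with origin 20
years and left truncation at the entry age. The hazard for event type k is
proportional-hazards Weibull with a log-quadratic age modulation:

    h(a | x) = (k/σ) ((a-20)/σ)^(k-1) · exp(β_a z + β_aa z²) · exp(x'β),   z = (a-50)/10

with covariates sex and BMI category (plus four comorbidity indicators for
mortality). This honours the conventional covariate list (age, age², sex, BMI) while
making the fitted cumulative hazard H(a) directly usable for the model's annual
transition probabilities p(a) = 1 - exp(-[H(a+1) - H(a)]): a survival model on
time-on-register with baseline-age covariates cannot be converted to an age-specific
annual probability without an arbitrary reference time, so the age timescale was
adopted as the package's design choice.

**Likelihood.** Fits are maximum likelihood with right censoring and left truncation;
the incidence analysis for each comorbidity censors at the first comorbidity of any
type, death, or record end; the mortality analysis splits each record into pre- and
post-onset episodes so the comorbidity indicator is handled exactly. Cumulative
hazards are computed by composite Gauss-Legendre quadrature in t = log v with
v = ((a-20)/σ)^k (5 log-spaced panels x 16 nodes): the substitution removes the
power-law endpoint behaviour and the log spacing bounds the panel-wise exponent
variation, which matters because an optimiser will otherwise exploit systematic
quadrature error at extreme shapes. log(a-20), z and z² are nearly collinear over a
typical entry-age span, so the power law and the log-quadratic terms trade off along a
likelihood ridge; a weak ridge penalty (N(0, ~0.7) prior on β_a, β_aa), box bounds
(shape in [e^-2, e^2], |β_a| <= 2, |β_aa| <= 1), and a two-stage fit (modulation frozen,
then released) keep the optimum in the interpretable part of the family. The observed
covariance is an eigenvalue-floored inverse Hessian, so flat ridge directions receive
honestly enormous standard errors; the hazard *function* — the quantity the decision
model consumes — is well identified wherever the data have events.

**Evidence tables.** Annual transition probabilities are model-smoothed (evaluated
from the fits on the full age 20–99 x sex x BMI x source-state grid — raw single-year
stratum counts are far too sparse), with effective n taken from the observed stratum
exposure in person-years. Strata with zero exposure get the fit's prediction with
n = 1, the maximally diffuse beta input, and are logged.

**Costs.** Two-part model per state class, age band (20–39, 40–59, 60–79, 80–100) and
sex: part 1 is the fraction of person-years with any cost (with counts kept for beta
sampling); part 2 a gamma fit to the positive amounts by maximum likelihood with a
method-of-moments fallback. Expected annual cost = part1 x part2 mean. Cells with
fewer than 10 person-years fall back to the class-level estimate (logged).

## The synthetic cohort generator

The generator emulates the *statistical structure* the estimators assume, not any real
population: per-person sex, entry age (right-skewed beta profile over 20–100,
register-like), deprivation quintile (independent of risk — no joint distribution is
published, so deprivation subgroups differ only by sampling noise unless the user
supplies dependence), Weibull event and death times drawn by inverse transform with
left truncation (exact closed form when the age modulation is absent, fine-grid
inversion otherwise), first-event censoring of the incidence record, post-onset
mortality re-drawn under the comorbid hazard (exact multistate simulation), depression
flags by state-class prevalence, and two-part annual costs in the person's current
state. Administrative follow-up is lognormal (log-SD 1.11, matching a wide
interquartile range); because records end at the earliest of record end, comorbidity
onset and death, the lognormal median is calibrated by bisection on the cohort's own
simulated endpoint times so that the *analysis-time* median hits the configured target
(5.6 years by default, the reported median of the 2008–2013 extract it emulates).

Default truth parameters (hazard scales, BMI gradients, cost means, depression
prevalences) were chosen once to give annual risks, life expectancies and costs of
plausible UK-adult magnitude with a strong BMI gradient for diabetes; they are not
calibrated to any real cohort's (unpublished) fitted estimates.
Consequently the synthetic world's headline outputs (incremental QALYs,
costs, ICER) are internally consistent but are *not* expected to reproduce the
published headline values; what passing tests show is that every pipeline stage recovers
its inputs and satisfies its invariants, not that the synthetic world equals the CPRD
world. Features of real EHR data the generator does not emulate include: informative
censoring, measurement error and misclassification, within-person cost autocorrelation,
secular trends, multimorbidity beyond the first event, and deprivation-linked risk.

## Numerical choices

- Quadrature: composite log-spaced Gauss-Legendre (see above); annual-probability
  values agree with adaptive quadrature of the hazard to better than 1e-8.
- Optimisation: L-BFGS-B with box bounds and a two-stage start; non-convergence is
  flagged on the returned fit and warned, never silently ignored.
- Beta draws at r in {0, n} get the +1/2 continuity correction; competing-incidence
  draws whose sum exceeds 1 (possible only in maximally diffuse strata) are
  renormalised with a logged warning.
- Utility clamp at 1.0; the surgical utility benefit is additive.
- Seeds: every stochastic stage takes a single integer seed; paired-arm and per-draw
  streams are derived with `numpy.random.SeedSequence.spawn`, so runs are bit-for-bit
  reproducible.

## Problem sizes

Default analysis sizes were chosen so a full pipeline run completes in minutes on a
single core: 30,000-person estimation cohorts and 50 PSA draws for the bundled
acceptance run (the cohort engine itself is deterministic in the occupancy masses, so
the 200,000-person entry population costs nothing extra); tests use 10,000–20,000
person cohorts for parameter recovery. All sizes are configuration fields, and scale
up linearly.

## Known limitations

- Deprivation subgroup runs are structurally supported but statistically inert under
  the default generator (see above).
- Depression relative risks beyond post-operative year 3, and BMI-category transition
  rates, have no published values; the package's defaults (carry-forward; identity)
  are documented choices, both overridable.
- The ICER CI uses the percentile distribution of per-draw ratios, which is unstable
  if any draw's ΔQ approaches zero; for the effect sizes modelled here this does not
  occur.
- Individual Weibull parameters are only weakly identified along the
  baseline-vs-age-modulation ridge; inference should be read on the hazard scale.
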