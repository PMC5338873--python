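"""State space, initial population, transition rows, intervention, utilities, costs."""

import numpy as np
import pytest

from baricea.estimation import DomainError, WeibullFit, annual_probability
from baricea.model_core import (
    DEAD_INDEX,
    N_STATES,
    InitialPopulationSpec,
    InterventionSpec,
    ModelState,
    UtilityTable,
    apply_intervention,
    apply_remission_and_operative_mortality,
    baseline_transition_row,
    build_initial_population,
    build_state_space,
    decay_multiplier,
    default_utility_table,
    effective_rr,
    state_cost,
    state_index,
    state_utility,
    surgery_utility_benefit,
)
from baricea.simulation import PSADraw
from baricea.synthetic_ehr import BMI_CATEGORIES, WeibullTruth, default_baseline_hazards


def _random_draw(seed=0, scale=0.05):
    rng = np.random.default_rng(seed)
    return PSADraw(
        seed=seed,
        p_incidence=rng.uniform(0, scale, size=(80, 2, 5, 4)),
        p_death=rng.uniform(0, scale, size=(80, 2, 5, 5)),
        cost_means=rng.uniform(100, 5000, size=(5, 4, 2)),
        depression_prev=rng.uniform(0, 0.4, size=5),
        utility_shift=np.zeros(5),
        rr_incidence={"diabetes": 0.2, "chd": 0.67, "stroke": 0.67, "cancer": 0.58},
        rr_mortality=0.45,
        rr_depression={1: 0.82, 2: 0.83, 3: 0.87},
    )


class TestStateSpace:
    def test_exactly_101_states(self):
        states = build_state_space()
        assert len(states) == N_STATES == 101
        assert len(set(map(str, states))) == 101

    def test_fifty_live_states_per_arm(self):
        states = build_state_space()
        for arm in ("surgery", "no_surgery"):
            assert sum(1 for s in states if not s.dead and s.arm == arm) == 50

    def test_dead_last_and_absorbing(self):
        states = build_state_space()
        assert states[-1].dead
        row = baseline_transition_row(states[-1], 50, 0, _random_draw())
        expected = np.zeros(101)
        expected[DEAD_INDEX] = 1.0
        np.testing.assert_array_equal(row, expected)


class TestInitialPopulation:
    def test_base_case_counts(self):
        occ = build_initial_population(InitialPopulationSpec())
        assert occ.sum() == pytest.approx(200_000, abs=1e-6)
        # disease marginals match the configured mix
        assert occ[..., 1].sum() == pytest.approx(38_462, abs=1e-6)
        assert occ[..., 2].sum() == pytest.approx(7_692, abs=1e-6)
        # all mass in the configured BMI category, split evenly by sex
        assert occ[:, :, 4, :].sum() == pytest.approx(200_000, abs=1e-6)
        assert occ[0].sum() == pytest.approx(100_000, abs=1e-6)
        # ages within 20..74
        ages = np.arange(20, 101)
        occupied = np.nonzero(occ.sum(axis=(0, 2, 3)))[0]
        assert ages[occupied].min() >= 20 and ages[occupied].max() <= 74

    def test_zero_population(self):
        spec = InitialPopulationSpec(total=0, n_men=0, n_women=0,
                                     disease_counts={"at_risk": 0})
        assert build_initial_population(spec).sum() == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            InitialPopulationSpec(disease_counts={"at_risk": 1})


class TestTransitionRows:
    def test_rows_sum_to_one_many_draws(self):
        states = build_state_space()
        live = [s for s in states if not s.dead][::7]
        for seed in range(40):
            draw = _random_draw(seed, scale=0.2)
            for s in live:
                row = baseline_transition_row(s, 20 + (seed * 3) % 80, seed % 2, draw)
                assert abs(row.sum() - 1.0) < 1e-12
                assert (row >= 0).all()

    def test_zero_hazards_mean_stay(self):
        draw = _random_draw(0, scale=0.0)
        s = ModelState("no_surgery", ">=40", "at_risk", False)
        row = baseline_transition_row(s, 46, 0, draw)
        assert row[state_index("no_surgery", 4, 0, False)] == pytest.approx(1.0)

    def test_death_higher_with_comorbidity(self):
        """Positive comorbidity coefficients imply a higher annual death probability
        from the diabetes state than from at risk."""
        fit = WeibullFit.from_truth(default_baseline_hazards()["death"], "death")
        p_ar = annual_probability(fit, {"sex": 0, "bmi": 4}, 60.0)
        p_dm = annual_probability(fit, {"sex": 0, "bmi": 4, "comorbidity": 0}, 60.0)
        assert p_dm > p_ar


class TestIntervention:
    def test_identity_effects_leave_row_unchanged(self):
        draw = _random_draw(3, scale=0.1)
        s = ModelState("surgery", ">=40", "at_risk", False)
        row = baseline_transition_row(s, 50, 0, draw)
        out = apply_intervention(row, s, InterventionSpec.null(), post_op_year=1)
        np.testing.assert_allclose(out, row, atol=1e-15)

    def test_rr_multiplies_incidence(self):
        draw = _random_draw(0, scale=0.0)
        draw.p_incidence[30, 0, 4, 0] = 0.10  # diabetes incidence at age 50
        s = ModelState("surgery", ">=40", "at_risk", False)
        row = baseline_transition_row(s, 50, 0, draw)
        out = apply_intervention(row, s, InterventionSpec(), post_op_year=1, sex=0)
        j = state_index("surgery", 4, 1, False)
        assert out[j] == pytest.approx(0.02)  # 0.10 * RR 0.20
        assert abs(out.sum() - 1.0) < 1e-12

    def test_cancer_rr_not_applied_to_men(self):
        draw = _random_draw(0, scale=0.0)
        draw.p_incidence[30, 1, 4, 3] = 0.05  # cancer incidence, male
        s = ModelState("surgery", ">=40", "at_risk", False)
        row = baseline_transition_row(s, 50, 1, draw)
        out = apply_intervention(row, s, InterventionSpec(), post_op_year=1, sex=1)
        j = state_index("surgery", 4, 4, False)
        assert out[j] == pytest.approx(0.05)  # unchanged for men
        out_f = apply_intervention(row, s, InterventionSpec(), post_op_year=1, sex=0)
        assert out_f[j] == pytest.approx(0.05 * 0.58)


class TestDecay:
    def test_year_one_is_unity(self):
        for e in (0.0, -0.25, -0.50):
            assert decay_multiplier(1, e) == 1.0

    def test_printed_declines_at_year_ten(self):
        assert 1 - decay_multiplier(10, -0.25) == pytest.approx(0.44, abs=0.005)
        assert 1 - decay_multiplier(10, -0.50) == pytest.approx(0.68, abs=0.005)

    def test_strictly_decreasing_for_negative_exponent(self):
        vals = [decay_multiplier(y, -0.25) for y in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_year_below_one_rejected(self):
        with pytest.raises(DomainError):
            decay_multiplier(0, -0.25)

    def test_effective_rr_attenuates_toward_one(self):
        assert effective_rr(0.2, 1, -0.25) == pytest.approx(0.2)
        assert effective_rr(0.2, 10, -0.25) == pytest.approx(1 - 0.8 * 10 ** -0.25)
        assert effective_rr(0.2, 5, None) == 0.2


class TestRemissionAndOperativeMortality:
    def test_forty_percent_remission(self):
        occ = np.zeros((2, 81, 5, 5))
        occ[0, 26, 4, 1] = 1000.0  # diabetes entrants
        spec = InterventionSpec(operative_mortality=0.0)
        out, deaths = apply_remission_and_operative_mortality(occ, spec)
        assert out[0, 26, 4, 0] == pytest.approx(400.0)
        assert out[0, 26, 4, 1] == pytest.approx(600.0)
        assert deaths == 0.0

    def test_operative_mortality_count(self):
        occ = np.zeros((2, 81, 5, 5))
        occ[:, 26, 4, 0] = 100_000.0  # 200,000 entrants
        _, deaths = apply_remission_and_operative_mortality(occ, InterventionSpec())
        assert deaths == pytest.approx(140.0)

    def test_null_leaves_occupancy(self):
        occ = np.zeros((2, 81, 5, 5))
        occ[1, 30, 4, 1] = 500.0
        out, deaths = apply_remission_and_operative_mortality(occ, InterventionSpec.null())
        np.testing.assert_array_equal(out, occ)
        assert deaths == 0.0


class TestUtility:
    def test_surgery_benefit_magnitude_and_decay(self):
        table = default_utility_table()
        assert surgery_utility_benefit(table) == pytest.approx(0.17)
        s = ModelState("surgery", ">=40", "at_risk", False)
        n = ModelState("no_surgery", ">=40", "at_risk", False)
        u1 = state_utility(s, 46, table, post_op_year=1)
        u0 = state_utility(n, 46, table)
        assert u1 - u0 == pytest.approx(0.17)
        u16 = state_utility(s, 46, table, post_op_year=16)
        assert u16 - u0 == pytest.approx(0.17 * 16 ** -0.25)
        assert u16 - u0 == pytest.approx(0.085, abs=1e-6)

    def test_bmi_decrement_applied(self):
        table = default_utility_table()
        hi = state_utility(ModelState("no_surgery", "18.5-25", "at_risk", False), 46, table)
        lo = state_utility(ModelState("no_surgery", ">=40", "at_risk", False), 46, table)
        assert hi - lo == pytest.approx(0.255)

    def test_clamped_at_one(self):
        base = np.ones(81)
        table = UtilityTable(base_by_age=base, disease_decrements={"at_risk": 0.0},
                             depression_decrement=0.0,
                             bmi_decrements=(0.0, 0.0, -0.085, -0.17, -0.255))
        s = ModelState("surgery", "18.5-25", "at_risk", False)
        assert state_utility(s, 30, table, post_op_year=1) == 1.0

    def test_depression_decrement(self):
        table = default_utility_table()
        d = state_utility(ModelState("no_surgery", ">=40", "diabetes", True), 50, table)
        nd = state_utility(ModelState("no_surgery", ">=40", "diabetes", False), 50, table)
        assert nd - d == pytest.approx(0.12)


class TestCosts:
    def test_procedure_cost_components(self):
        spec = InterventionSpec()
        assert spec.total_procedure_cost == pytest.approx(9164.0)
        assert spec.tariff_average == pytest.approx((3620 + 8713 + 8713) / 3)
        assert round(spec.tariff_average) == 7015
        assert spec.expected_reoperation_cost == pytest.approx(72.40)

    def test_state_cost_arms(self):
        means = np.full((5, 4, 2), 1000.0)
        spec = InterventionSpec()
        n = ModelState("no_surgery", ">=40", "diabetes", False)
        s = ModelState("surgery", ">=40", "diabetes", False)
        assert state_cost(n, 50, 0, means) == 1000.0
        assert state_cost(s, 50, 0, means, post_op_year=1, spec=spec) == 1000.0 + 9164.0
        assert state_cost(s, 51, 0, means, post_op_year=2, spec=spec) == pytest.approx(1072.40)

    def test_negative_cost_rejected(self):
        means = np.full((5, 4, 2), -1.0)
        with pytest.raises(ValueError):
            state_cost(ModelState("no_surgery", ">=40", "at_risk", False), 50, 0, means)
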