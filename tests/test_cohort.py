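"""Cohort dynamics: transition matrices, state values, traces, engine parity."""

import numpy as np
import pytest

from conftest import (certain_death_table, constant_prevalence,
                      zero_mortality_table)
from smokece.cohort import (CURRENT, DEAD, FORMER, build_transition_matrix,
                            discount_factor, run_cohort, state_cost,
                            state_utility)
from smokece.engine import batch_inputs_from_means, run_batch
from smokece.model import evaluate_arm, evaluate_comparison
from smokece.params import TransitionRates
from smokece.reference import ReferenceBundle


@pytest.fixture()
def no_mortality_surfaces(surfaces):
    return ReferenceBundle(zero_mortality_table(), surfaces.prevalence,
                           surfaces.weights)


class TestDiscountFactor:
    @pytest.mark.parametrize("t,rate,expected", [
        (0, 0.035, 1.0),
        (1, 0.035, 1.0 / 1.035),   # 0.966184
        (5, 0.0, 1.0),
    ])
    def test_values(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestTransitionMatrix:
    BASE_RATES = TransitionRates((0.02, 0.003), (0.0, 0.0))

    def test_current_row_base_case_no_mortality(self):
        m = build_transition_matrix(1, 40, "male", 0.173, self.BASE_RATES,
                                    zero_mortality_table(), 2.22)
        assert m[CURRENT] == pytest.approx([0.98, 0.02, 0.0])

    def test_former_row_base_case_no_mortality(self):
        m = build_transition_matrix(1, 40, "male", 0.173, self.BASE_RATES,
                                    zero_mortality_table(), 2.22)
        assert m[FORMER] == pytest.approx([0.0, 1.0, 0.0])

    def test_cycle_zero_uses_arm_effect(self):
        m = build_transition_matrix(0, 40, "female", 0.173, self.BASE_RATES,
                                    zero_mortality_table(), 1.0)
        assert m[CURRENT] == pytest.approx([0.827, 0.173, 0.0])

    def test_death_competes_first(self, surfaces):
        age, sex, rr = 70, "male", 2.22
        m = build_transition_matrix(1, age, sex, 0.173, self.BASE_RATES,
                                    surfaces.life_table, rr)
        d = min(1.0, surfaces.life_table.q(age, sex, "current") * rr)
        assert m[CURRENT, FORMER] == pytest.approx((1 - d) * 0.02, rel=1e-12)
        assert m[CURRENT, DEAD] == pytest.approx(d, rel=1e-12)

    def test_rows_stochastic_for_random_inputs(self, surfaces):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rates = TransitionRates((rng.uniform(0, 1), 0.0),
                                    (rng.uniform(0, 1), 0.0))
            m = build_transition_matrix(
                int(rng.integers(0, 5)), int(rng.integers(12, 100)),
                "female", rng.uniform(0, 1), rates, surfaces.life_table,
                rng.uniform(0.5, 3.0))
            assert m.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0], abs=1e-12)
            assert np.all(m >= 0)


class TestStateValues:
    def test_utility_zero_prevalence_current_smoker(self, params):
        surf = constant_prevalence(params.comorbidities)
        u = state_utility(CURRENT, 40, "male", params, surf)
        assert u == pytest.approx(0.88 - 0.04 - 0.125)  # 0.715

    def test_utility_zero_prevalence_zero_decrements(self, params):
        import dataclasses
        p = dataclasses.replace(
            params,
            utilities=dataclasses.replace(
                params.utilities, decrement_current=(0.0, 0.0),
                smi_decrement=(0.0, 0.0)))
        surf = constant_prevalence(p.comorbidities)
        assert state_utility(CURRENT, 40, "male", p, surf) == \
            pytest.approx(0.88)

    def test_utility_full_stroke_prevalence_former(self, params):
        surf = constant_prevalence(params.comorbidities,
                                   overrides={"stroke": (1.0, 1.0)})
        u = state_utility(FORMER, 60, "female", params, surf)
        # 0.88 - 0.02 - 0.125 - (0.88 - 0.48)
        assert u == pytest.approx(0.335)

    def test_dead_state_rejected(self, params):
        surf = constant_prevalence(params.comorbidities)
        with pytest.raises(ValueError):
            state_utility(DEAD, 40, "male", params, surf)
        with pytest.raises(ValueError):
            state_cost(DEAD, 40, "male", params, surf)

    def test_cost_zero_prevalence(self, params):
        surf = constant_prevalence(params.comorbidities)
        assert state_cost(CURRENT, 40, "male", params, surf) == 0.0

    def test_cost_half_copd_prevalence(self, params):
        surf = constant_prevalence(params.comorbidities,
                                   overrides={"copd": (0.5, 0.5)})
        assert state_cost(CURRENT, 40, "male", params, surf) == \
            pytest.approx(0.5 * 636)  # 318


class TestRunCohort:
    def test_trace_invariants(self, params, surfaces):
        tr = run_cohort(40, "male", "bsci", params, surfaces)
        occ = tr.occupancy()
        assert occ.sum(axis=1) == pytest.approx(np.ones(len(occ)), abs=1e-10)
        assert np.all(np.diff(occ[:, DEAD]) >= -1e-12)
        f = tr.frame
        later = f[f.cycle >= 1]
        assert np.all(later.cost_comorbidity_disc <= later.cost_comorbidity + 1e-12)
        assert np.all(later.qaly_disc <= later.qaly + 1e-12)

    def test_no_quitting_means_no_former_smokers(self, params,
                                                 no_mortality_surfaces):
        p = params.with_transitions(0.0, 0.0)
        tr = run_cohort(30, "female", "bsci", p, no_mortality_surfaces,
                        quit_prob=0.0)
        assert np.all(tr.occupancy()[:, FORMER] == 0.0)

    def test_certain_death_at_entry(self, params, surfaces):
        deadly = ReferenceBundle(certain_death_table(), surfaces.prevalence,
                                 surfaces.weights)
        tr = run_cohort(40, "male", "bsci", params, deadly)
        occ = tr.occupancy()
        assert occ[1:, DEAD] == pytest.approx(np.ones(len(occ) - 1))
        # totals reduce to the cycle-0 accruals
        assert tr.total_cost_discounted == pytest.approx(
            tr.frame.loc[0, "cost_intervention"] + tr.frame.loc[0, "cost_comorbidity"])
        assert tr.total_qalys_discounted == pytest.approx(tr.frame.loc[0, "qaly"])

    def test_horizon_validation(self, params, surfaces):
        with pytest.raises(ValueError):
            run_cohort(40, "male", "bsci", params, surfaces, horizon=0)
        with pytest.raises(ValueError):
            run_cohort(5, "male", "bsci", params, surfaces)

    def test_equal_effectiveness_isolates_intervention_cost(self, params,
                                                            surfaces):
        res = evaluate_comparison("bsci_vs_uc", params, surfaces,
                                  quit_probs={"bsci": 0.12, "usual_care": 0.12})
        assert res.delta_qalys == 0.0
        assert res.delta_cost_comorbidity == 0.0
        assert res.delta_cost == pytest.approx(581 - 96)

    def test_monotone_in_quit_probability(self, params, surfaces):
        outs = [evaluate_arm("bsci", params, surfaces, quit_prob=q)
                for q in (0.0, 0.1, 0.2, 0.4)]
        qalys = [o.qalys for o in outs]
        costs = [o.cost_comorbidity for o in outs]
        assert np.all(np.diff(qalys) >= 0)
        assert np.all(np.diff(costs) <= 0)

    def test_neutral_smi_reduces_to_general_population_structure(
            self, params, surfaces):
        import dataclasses
        neutral = dataclasses.replace(
            params,
            smi=dataclasses.replace(params.smi, rr_mortality=(1.0, 0.0),
                                    or_comorbidity=(1.0, 0.0)),
            utilities=dataclasses.replace(params.utilities,
                                          smi_decrement=(0.0, 0.0)))
        tr = run_cohort(50, "male", "bsci", neutral, surfaces)
        # cycle 0: everyone a current smoker; utility must equal the
        # general-population rule with *unadjusted* prevalence
        base = params.utilities.base_nonsmoker[0]
        expected = base - params.utilities.decrement_current[0]
        for cond, cp in params.comorbidities.items():
            prev = float(surfaces.prevalence.prevalence(cond, 50, "male",
                                                        "current"))
            expected -= prev * (base - cp.utility_mean)
        assert tr.frame.loc[0, "qaly"] == pytest.approx(expected, rel=1e-12)


class TestEngineParity:
    def test_batch_engine_matches_trace_totals(self, params, surfaces):
        inputs = batch_inputs_from_means(params, surfaces, "integrated_care")
        res = run_batch(inputs)
        for age, sex in [(12, "female"), (55, "male"), (100, "female")]:
            tr = run_cohort(age, sex, "integrated_care", params, surfaces)
            i, j = age - 12, ("female", "male").index(sex)
            assert res.comorbidity_cost[0, i, j] == pytest.approx(
                tr.total_cost_comorbidity, abs=1e-8)
            assert res.qalys[0, i, j] == pytest.approx(
                tr.total_qalys_discounted, abs=1e-10)

    def test_batch_engine_matches_trace_with_horizon(self, params, surfaces):
        inputs = batch_inputs_from_means(params, surfaces, "bsci")
        res = run_batch(inputs, horizon=5)
        tr = run_cohort(40, "male", "bsci", params, surfaces, horizon=5)
        assert res.qalys[0, 28, 1] == pytest.approx(tr.total_qalys_discounted,
                                                    abs=1e-10)
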