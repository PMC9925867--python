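"""PSA sampling, CEAC consistency, tornado analysis, scenario variants."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import degenerate
from smokece.model import evaluate_comparison
from smokece.uncertainty import (ScenarioConfig, _set_parameter, apply_scenario,
                                 run_dsa, run_psa, run_scenario,
                                 sample_iteration, sample_parameter_arrays)


def scale_sds(ps, factor):
    """Parameter set with every SD multiplied by ``factor``."""
    rep = dataclasses.replace
    s2 = lambda pair: (pair[0], pair[1] * factor)
    return rep(
        ps,
        effectiveness={a: rep(e, sd=e.sd * factor)
                       for a, e in ps.effectiveness.items()},
        comorbidities={c: rep(p, annual_cost_sd=p.annual_cost_sd * factor,
                              utility_sd=p.utility_sd * factor)
                       for c, p in ps.comorbidities.items()},
        utilities=rep(ps.utilities,
                      base_nonsmoker=s2(ps.utilities.base_nonsmoker),
                      decrement_current=s2(ps.utilities.decrement_current),
                      decrement_former=s2(ps.utilities.decrement_former),
                      smi_decrement=s2(ps.utilities.smi_decrement)),
        smi=rep(ps.smi, rr_mortality=s2(ps.smi.rr_mortality),
                or_comorbidity=s2(ps.smi.or_comorbidity),
                smi_disutility=s2(ps.smi.smi_disutility)),
        transitions=rep(ps.transitions,
                        net_cessation=s2(ps.transitions.net_cessation),
                        relapse=s2(ps.transitions.relapse)),
    )


class TestSampling:
    def test_all_degenerate_returns_identical_set(self, params):
        fixed = degenerate(params)
        drawn = sample_iteration(fixed, np.random.default_rng(0))
        assert drawn == fixed

    def test_fixed_seed_reproducible(self, params):
        a = sample_iteration(params, np.random.default_rng(5))
        b = sample_iteration(params, np.random.default_rng(5))
        assert a == b

    def test_copd_cost_mean_recovery(self, params):
        n = 100_000
        draws = sample_parameter_arrays(params, n, np.random.default_rng(0))
        x = draws["cost:copd"]
        assert abs(x.mean() - 636.0) < 3.0 * 95.0 / math.sqrt(n)

    def test_sampled_probabilities_stay_in_unit_interval(self, params):
        draws = sample_parameter_arrays(params, 2000, np.random.default_rng(1))
        for name, x in draws.items():
            if name.startswith(("effectiveness", "utility", "decrement",
                                "transition")):
                assert np.all((x >= 0) & (x <= 1)), name


class TestPSA:
    def test_degenerate_psa_reproduces_deterministic(self, params, surfaces):
        fixed = degenerate(params)
        det = evaluate_comparison("bsci_vs_uc", fixed, surfaces)
        psa = run_psa(fixed, surfaces, "bsci_vs_uc", n_iterations=20, seed=0)
        assert psa.mean_delta_cost == pytest.approx(det.delta_cost, abs=1e-9)
        assert psa.mean_delta_qalys == pytest.approx(det.delta_qalys, abs=1e-12)
        assert psa.sd_delta_cost == pytest.approx(0.0, abs=1e-9)
        assert psa.probabilistic_icer == pytest.approx(det.icer, rel=1e-9)

    def test_strictly_better_intervention_certain(self, params, surfaces):
        fixed = degenerate(params)
        # make the intervention cheaper than its comparator outright
        costs = dict(fixed.intervention_costs)
        costs["bsci"] = dataclasses.replace(costs["bsci"], total=10.0,
                                            components={"delivery": 10.0})
        better = dataclasses.replace(fixed, intervention_costs=costs)
        psa = run_psa(better, surfaces, "bsci_vs_uc", n_iterations=10, seed=0)
        assert psa.prob_cost_effective() == 1.0

    def test_strictly_worse_intervention_certain(self, params, surfaces):
        fixed = degenerate(params)
        eff = dict(fixed.effectiveness)
        eff["bsci"] = dataclasses.replace(eff["bsci"], quit_prob_12m=0.01)
        worse = dataclasses.replace(fixed, effectiveness=eff)
        psa = run_psa(worse, surfaces, "bsci_vs_uc", n_iterations=10, seed=0)
        assert psa.prob_cost_effective() == 0.0

    def test_ceac_consistent_with_point_probability(self, model):
        psa = model.run_psa("bsci_vs_uc", n_iterations=200, seed=3)
        ceac = psa.ceac
        for thr in (0.0, 10_000.0, 20_000.0, 50_000.0):
            row = ceac.loc[ceac.threshold == thr, "probability"].iloc[0]
            assert row == psa.prob_cost_effective(thr)

    def test_probabilistic_icer_converges_to_deterministic(self, params,
                                                           surfaces):
        det = evaluate_comparison("bsci_vs_uc", params, surfaces)
        shrunk = scale_sds(params, 1e-4)
        psa = run_psa(shrunk, surfaces, "bsci_vs_uc", n_iterations=200, seed=0)
        assert psa.probabilistic_icer == pytest.approx(det.icer, rel=1e-2)

    def test_iteration_frame_shape(self, model):
        psa = model.run_psa("ic_vs_scc", n_iterations=50, seed=1)
        frame = psa.iterations_frame()
        assert len(frame) == 100
        assert set(frame.arm) == {"integrated_care", "scc_referral"}

    def test_invalid_iteration_count(self, params, surfaces):
        with pytest.raises(ValueError):
            run_psa(params, surfaces, "bsci_vs_uc", n_iterations=0)


class TestDSA:
    def test_degenerate_parameter_leaves_icer_unchanged(self, params,
                                                        surfaces):
        base = evaluate_comparison("bsci_vs_uc", params, surfaces)
        entries = run_dsa(params, surfaces, "bsci_vs_uc",
                          parameter_names=["transition:relapse"])
        e = entries[0]
        assert e.low == e.high == params.transitions.relapse[0]
        assert e.result_low.icer == pytest.approx(base.icer)

    def test_null_perturbation_recovers_base_icer(self, params, surfaces):
        base = evaluate_comparison("bsci_vs_uc", params, surfaces)
        for name in sorted(params.distribution_specs()):
            same = _set_parameter(params, name,
                                  params.distribution_specs()[name].mean)
            res = evaluate_comparison("bsci_vs_uc", same, surfaces)
            assert res.icer == pytest.approx(base.icer, rel=1e-9), name

    def test_lower_effectiveness_bound_dominated_not_negative(self, params,
                                                              surfaces):
        # an intervention whose lower 95% bound drops below the comparator
        eff = dict(params.effectiveness)
        eff["bsci"] = dataclasses.replace(eff["bsci"], quit_prob_12m=0.13,
                                          sd=0.03)
        wide = dataclasses.replace(params, effectiveness=eff)
        entries = run_dsa(wide, surfaces, "bsci_vs_uc",
                          parameter_names=["effectiveness:bsci"])
        low_result = entries[0].result_low
        assert entries[0].low < params.effectiveness["usual_care"].quit_prob_12m
        assert low_result.classification == "dominated"
        assert low_result.icer is None
        assert entries[0].icer_low == "Dominated"

    def test_wider_sd_widens_tornado_bar(self, params, surfaces):
        narrow = run_dsa(params, surfaces, "bsci_vs_uc",
                         parameter_names=["cost:copd"])[0]
        com = dict(params.comorbidities)
        com["copd"] = dataclasses.replace(com["copd"], annual_cost_sd=190.0)
        wide_params = dataclasses.replace(params, comorbidities=com)
        wide = run_dsa(wide_params, surfaces, "bsci_vs_uc",
                       parameter_names=["cost:copd"])[0]
        assert wide.nmb_range > narrow.nmb_range

    def test_default_list_sorted_by_influence(self, params, surfaces):
        entries = run_dsa(params, surfaces, "ic_vs_scc")
        ranges = [e.nmb_range for e in entries]
        assert ranges == sorted(ranges, reverse=True)
        names = {e.parameter for e in entries}
        assert "effectiveness:integrated_care" in names
        assert "effectiveness:bsci" not in names  # other comparison's arm
        assert "transition:relapse" not in names  # zero SD


class TestScenarios:
    def test_scenario3_with_base_rates_is_identity(self, params, surfaces):
        base = run_scenario(ScenarioConfig.base(), params, surfaces)
        s3 = run_scenario(ScenarioConfig.scenario3(cessation=0.02, relapse=0.0),
                          params, surfaces)
        assert s3.delta_cost == pytest.approx(base.delta_cost, abs=1e-9)
        assert s3.delta_qalys == pytest.approx(base.delta_qalys, abs=1e-12)

    def test_scenario2_zero_addons_is_identity(self, params, surfaces):
        zeroed = dataclasses.replace(
            params, service_utilisation={a: 0.0 for a in params.effectiveness})
        base = run_scenario(ScenarioConfig.base(), zeroed, surfaces)
        s2 = run_scenario(ScenarioConfig.scenario2(), zeroed, surfaces)
        assert s2.delta_cost == pytest.approx(base.delta_cost, abs=1e-9)

    def test_scenario2_moves_addons_into_intervention_costs(self, params,
                                                            surfaces):
        s2 = run_scenario(ScenarioConfig.scenario2(), params, surfaces,
                          "bsci_vs_uc")
        assert s2.intervention.cost_intervention == pytest.approx(581 + 7903)
        assert s2.comparator.cost_intervention == pytest.approx(96 + 8667)

    def test_scenario1_requires_self_report_inputs(self, params, surfaces):
        stripped = dataclasses.replace(params, self_report_effectiveness=None)
        with pytest.raises(ValueError, match="self-report"):
            run_scenario(ScenarioConfig.scenario1(), stripped, surfaces)

    def test_five_year_horizon_shrinks_qaly_gain(self, params, surfaces):
        lifetime = run_scenario(ScenarioConfig.base(), params, surfaces)
        short = run_scenario(ScenarioConfig.base(horizon=5), params, surfaces)
        assert short.delta_qalys < lifetime.delta_qalys

    def test_unknown_effectiveness_source_rejected(self, params):
        bad = ScenarioConfig(effectiveness_source="guess")
        with pytest.raises(ValueError):
            apply_scenario(params, bad)
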