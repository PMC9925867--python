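"""High-level model object tying parameters, surfaces and analyses together.

`CostEffectivenessModel` is the front door: build it from a validated
parameter set and a reference bundle (or from packaged defaults), then
call `evaluate()` for a deterministic comparison, `run_scenario()` for
the scenario analyses, `run_dsa()` for one-way sensitivity analysis and
`run_psa()` for the probabilistic analysis. Each call returns a result
object carrying the estimates and a `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .economics import ArmOutcome, CEResult, incremental_analysis
from .engine import batch_inputs_from_means, run_batch
from .params import COMPARISONS, ParameterSet, build_parameter_set
from .reference import ReferenceBundle

__all__ = ["CostEffectivenessModel", "evaluate_arm", "evaluate_comparison"]


def _aggregate_batch(result, weights, intervention_cost: float):
    """Collapse a (B, age, sex) batch result onto population weights."""
    w = weights.w / weights.w.sum()
    cost = result.comorbidity_cost.reshape(result.comorbidity_cost.shape[0], -1) \
        @ w.reshape(-1)
    qaly = result.qalys.reshape(result.qalys.shape[0], -1) @ w.reshape(-1)
    return cost, qaly, np.full_like(cost, intervention_cost)


def evaluate_arm(arm: str, params: ParameterSet, surfaces: ReferenceBundle,
                 horizon: int | None = None,
                 quit_prob: float | None = None) -> ArmOutcome:
    """Deterministic population-average lifetime outcome for one arm."""
    inputs = batch_inputs_from_means(params, surfaces, arm, quit_prob=quit_prob)
    result = run_batch(inputs, horizon=horizon)
    cost_c, qalys, _ = _aggregate_batch(
        result, surfaces.weights, params.intervention_costs[arm].total)
    qp = params.effectiveness[arm].quit_prob_12m if quit_prob is None else quit_prob
    return ArmOutcome(
        arm_name=arm,
        cost_intervention=params.intervention_costs[arm].total,
        cost_comorbidity=float(cost_c[0]),
        qalys=float(qalys[0]),
        quit_prob_12m=qp,
    ).validate()


def evaluate_comparison(comparison: str, params: ParameterSet,
                        surfaces: ReferenceBundle,
                        horizon: int | None = None,
                        threshold: float | None = None,
                        quit_probs: dict[str, float] | None = None) -> CEResult:
    """Deterministic incremental analysis for one named comparison."""
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; "
                         f"valid: {sorted(COMPARISONS)}")
    inter_arm, comp_arm = COMPARISONS[comparison]
    quit_probs = quit_probs or {}
    inter = evaluate_arm(inter_arm, params, surfaces, horizon,
                         quit_probs.get(inter_arm))
    comp = evaluate_arm(comp_arm, params, surfaces, horizon,
                        quit_probs.get(comp_arm))
    thr = params.threshold_gbp_per_qaly if threshold is None else threshold
    return incremental_analysis(inter, comp, thr)


@dataclass
class CostEffectivenessModel:
    """Lifetime Markov cohort cost-utility model for tailored smoking
    cessation in severe mental illness.

    Parameters
    ----------
    params
        Validated model inputs (defaults: the packaged transcriptions of
        the published input tables).
    surfaces
        Mortality / prevalence / population-weight reference surfaces
        (defaults: the synthetic generator at ``reference_seed``).
    """

    params: ParameterSet = field(default_factory=build_parameter_set)
    surfaces: ReferenceBundle | None = None
    reference_seed: int = 0

    def __post_init__(self):
        if self.surfaces is None:
            self.surfaces = ReferenceBundle.generate(self.reference_seed)

    @classmethod
    def from_defaults(cls, reference_seed: int = 0) -> "CostEffectivenessModel":
        return cls(reference_seed=reference_seed)

    def arm_outcome(self, arm: str, horizon: int | None = None) -> ArmOutcome:
        return evaluate_arm(arm, self.params, self.surfaces, horizon)

    def evaluate(self, comparison: str = "bsci_vs_uc",
                 horizon: int | None = None,
                 threshold: float | None = None) -> CEResult:
        return evaluate_comparison(comparison, self.params, self.surfaces,
                                   horizon, threshold)

    def run_scenario(self, scenario, comparison: str = "bsci_vs_uc") -> CEResult:
        from .uncertainty import run_scenario
        return run_scenario(scenario, self.params, self.surfaces, comparison)

    def run_dsa(self, comparison: str = "bsci_vs_uc", parameters=None):
        from .uncertainty import run_dsa
        return run_dsa(self.params, self.surfaces, comparison,
                       parameter_names=parameters)

    def run_psa(self, comparison: str = "bsci_vs_uc", n_iterations: int = 3000,
                seed: int | None = None, **kwargs):
        from .uncertainty import run_psa
        return run_psa(self.params, self.surfaces, comparison,
                       n_iterations=n_iterations, seed=seed, **kwargs)
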