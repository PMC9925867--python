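"""Probabilistic and deterministic sensitivity analysis, scenario analyses.

PSA: every uncertain parameter gets a moment-matched distribution
(lognormal for relative risks / odds ratios, beta for probabilities and
utilities, gamma for costs); each iteration draws a fresh parameter set,
re-evaluates both arms of a comparison, and the iteration cloud yields
the probability of cost-effectiveness and the cost-effectiveness
acceptability curve (CEAC). Shared parameters (mortality RR, comorbidity
OR, utilities, costs, transition rates) use common random numbers across
arms within an iteration; arm-level effectiveness is drawn independently
per arm. The probabilistic ICER is the ratio of mean increments, the
standard convention.

DSA: one-way tornado analysis moving each parameter to its 95% interval
bounds (mean ± 1.96·SD on the natural scale; the lognormal parameters
move on the log scale), clamped to the parameter's valid range.

Scenarios: (1) self-reported instead of biochemically validated
effectiveness; (2) 12-month healthcare service-utilisation costs folded
into intervention costs; (3) separate cessation (4.1%/yr, with the
published table's alternative 4.4% available via configuration) and
relapse (10%/yr) rates after the first year; plus a truncated-horizon
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult
from .engine import BatchInputs, run_batch
from .model import evaluate_comparison
from .params import COMPARISONS, DistributionSpec, ParameterSet
from .reference import STATUSES, ReferenceBundle

__all__ = [
    "ScenarioConfig",
    "PSAResult",
    "TornadoEntry",
    "apply_scenario",
    "run_scenario",
    "sample_parameter_arrays",
    "sample_iteration",
    "run_psa",
    "run_dsa",
]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One of the predefined scenario analyses, or a custom variant.

    ``net_cessation`` / ``relapse`` of ``None`` keep the parameter set's
    base-case values; ``horizon`` of ``None`` means lifetime.
    """

    scenario_id: str = "base"
    effectiveness_source: str = "validated"   # or "self_report"
    include_service_utilisation: bool = False
    net_cessation: float | None = None
    relapse: float | None = None
    horizon: int | None = None

    @classmethod
    def base(cls, horizon: int | None = None) -> "ScenarioConfig":
        return cls("base", horizon=horizon)

    @classmethod
    def scenario1(cls) -> "ScenarioConfig":
        """Self-reported (plus CO-validated) quitting as the outcome."""
        return cls("1", effectiveness_source="self_report")

    @classmethod
    def scenario2(cls) -> "ScenarioConfig":
        """Service-utilisation costs added to intervention costs."""
        return cls("2", include_service_utilisation=True)

    @classmethod
    def scenario3(cls, cessation: float = 0.041,
                  relapse: float = 0.10) -> "ScenarioConfig":
        """Separate cessation/relapse flows applied from 24 months on."""
        return cls("3", net_cessation=cessation, relapse=relapse)


def apply_scenario(params: ParameterSet, scenario: ScenarioConfig) -> ParameterSet:
    """Return the parameter set with the scenario's substitutions applied."""
    if scenario.effectiveness_source not in ("validated", "self_report"):
        raise ValueError(
            f"unknown effectiveness source {scenario.effectiveness_source!r}")
    out = params
    if scenario.effectiveness_source == "self_report":
        out = out.with_self_report_effectiveness()
    if scenario.include_service_utilisation:
        out = out.with_service_utilisation_costs()
    if scenario.net_cessation is not None or scenario.relapse is not None:
        ces = (out.transitions.net_cessation[0]
               if scenario.net_cessation is None else scenario.net_cessation)
        rel = (out.transitions.relapse[0]
               if scenario.relapse is None else scenario.relapse)
        out = out.with_transitions(ces, rel)
    return out


def run_scenario(scenario: ScenarioConfig, params: ParameterSet,
                 surfaces: ReferenceBundle,
                 comparison: str = "bsci_vs_uc",
                 threshold: float | None = None) -> CEResult:
    """Deterministic evaluation of a comparison under a scenario."""
    adjusted = apply_scenario(params, scenario)
    return evaluate_comparison(comparison, adjusted, surfaces,
                               horizon=scenario.horizon, threshold=threshold)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def sample_parameter_arrays(params: ParameterSet, n: int,
                            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw ``n`` values per uncertain parameter, keyed by parameter name.

    Draw order is the sorted key order, so a fixed generator state gives
    bit-identical output. Decrement magnitudes are returned (the sign is
    applied where the decrement is subtracted).
    """
    specs = params.distribution_specs()
    return {name: np.asarray(specs[name].sample(rng, size=n))
            for name in sorted(specs)}


def _set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one named parameter replaced."""
    if name.startswith("effectiveness:"):
        return params.with_effectiveness({name.split(":", 1)[1]: float(value)})
    if name.startswith("cost:"):
        cond = name.split(":", 1)[1]
        com = dict(params.comorbidities)
        com[cond] = replace(com[cond], annual_cost_mean=float(value))
        return replace(params, comorbidities=com)
    if name.startswith("utility:"):
        key = name.split(":", 1)[1]
        if key == "base_nonsmoker":
            u = replace(params.utilities,
                        base_nonsmoker=(float(value), params.utilities.base_nonsmoker[1]))
            return replace(params, utilities=u)
        com = dict(params.comorbidities)
        com[key] = replace(com[key], utility_mean=float(value))
        return replace(params, comorbidities=com)
    if name.startswith("decrement:"):
        key = name.split(":", 1)[1]
        u = params.utilities
        if key == "current":
            u = replace(u, decrement_current=(float(value), u.decrement_current[1]))
        elif key == "former":
            u = replace(u, decrement_former=(float(value), u.decrement_former[1]))
        elif key == "smi":
            u = replace(u, smi_decrement=(float(value), u.smi_decrement[1]))
            smi = replace(params.smi,
                          smi_disutility=(float(value), params.smi.smi_disutility[1]))
            return replace(params, utilities=u, smi=smi)
        else:
            raise KeyError(name)
        return replace(params, utilities=u)
    if name == "rr_mortality":
        smi = replace(params.smi,
                      rr_mortality=(float(value), params.smi.rr_mortality[1]))
        return replace(params, smi=smi)
    if name == "or_comorbidity":
        smi = replace(params.smi,
                      or_comorbidity=(float(value), params.smi.or_comorbidity[1]))
        return replace(params, smi=smi)
    if name == "transition:net_cessation":
        return params.with_transitions(float(value), params.transitions.relapse[0])
    if name == "transition:relapse":
        return params.with_transitions(params.transitions.net_cessation[0],
                                       float(value))
    raise KeyError(f"unknown parameter name {name!r}")


def sample_iteration(params: ParameterSet,
                     rng: np.random.Generator) -> ParameterSet:
    """One PSA draw of the whole parameter set (object form).

    With every SD equal to zero this returns the deterministic set
    exactly. The vectorised PSA path samples the same distributions in
    the same order; this object form exists for inspection and testing.
    """
    out = params
    specs = params.distribution_specs()
    for name in sorted(specs):
        out = _set_parameter(out, name, float(specs[name].sample(rng)))
    return out


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Iteration-level PSA output for one pairwise comparison."""

    comparison: str
    arms: tuple[str, str]
    costs: Mapping[str, np.ndarray]        # arm -> (n,) discounted total cost
    qalys: Mapping[str, np.ndarray]        # arm -> (n,)
    threshold: float
    ceac_grid: np.ndarray
    n_iterations: int
    seed: int | None

    @property
    def delta_costs(self) -> np.ndarray:
        return self.costs[self.arms[0]] - self.costs[self.arms[1]]

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys[self.arms[0]] - self.qalys[self.arms[1]]

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_costs.mean())

    @property
    def sd_delta_cost(self) -> float:
        return float(self.delta_costs.std(ddof=1))

    @property
    def mean_delta_qalys(self) -> float:
        return float(self.delta_qalys.mean())

    @property
    def sd_delta_qalys(self) -> float:
        return float(self.delta_qalys.std(ddof=1))

    @property
    def probabilistic_icer(self) -> float:
        """Ratio of mean increments (not the mean of iteration ratios)."""
        return self.mean_delta_cost / self.mean_delta_qalys

    def prob_cost_effective(self, threshold: float | None = None) -> float:
        """Fraction of iterations with positive net monetary benefit."""
        thr = self.threshold if threshold is None else threshold
        nmb = thr * self.delta_qalys - self.delta_costs
        return float(np.mean(nmb > 0.0))

    @property
    def ceac(self) -> pd.DataFrame:
        """Probability cost-effective across the willingness-to-pay grid."""
        probs = [self.prob_cost_effective(t) for t in self.ceac_grid]
        return pd.DataFrame({"threshold": self.ceac_grid, "probability": probs})

    def iterations_frame(self) -> pd.DataFrame:
        frames = []
        for arm in self.arms:
            frames.append(pd.DataFrame({
                "iteration": np.arange(self.n_iterations), "arm": arm,
                "cost": self.costs[arm], "qaly": self.qalys[arm],
            }))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        return "\n".join([
            f"PSA ({self.comparison}): {self.n_iterations} iterations, "
            f"seed {self.seed}",
            f"mean ΔC £{self.mean_delta_cost:,.0f} (SD £{self.sd_delta_cost:,.0f}); "
            f"mean ΔQ {self.mean_delta_qalys:.3f} (SD {self.sd_delta_qalys:.3f})",
            f"probabilistic ICER £{self.probabilistic_icer:,.0f}/QALY",
            f"P(cost-effective at £{self.threshold:,.0f}) = "
            f"{100 * self.prob_cost_effective():.0f}%",
        ])


def _batch_inputs_from_draws(params: ParameterSet, surfaces: ReferenceBundle,
                             arm: str, draws: Mapping[str, np.ndarray],
                             n: int) -> BatchInputs:
    conds = list(params.comorbidities)
    lt = surfaces.life_table.qx
    life_qx = lt[:, :, [STATUSES.index("current"), STATUSES.index("former")]]
    return BatchInputs(
        quit_prob=draws[f"effectiveness:{arm}"],
        cessation=draws["transition:net_cessation"],
        relapse=draws["transition:relapse"],
        rr_mortality=draws["rr_mortality"],
        or_comorbidity=draws["or_comorbidity"],
        comorbidity_costs=np.column_stack([draws[f"cost:{c}"] for c in conds]),
        comorbidity_utils=np.column_stack([draws[f"utility:{c}"] for c in conds]),
        base_utility=draws["utility:base_nonsmoker"],
        dec_current=draws["decrement:current"],
        dec_former=draws["decrement:former"],
        dec_smi=draws["decrement:smi"],
        smi_adjustable=np.asarray(
            [params.comorbidities[c].smi_adjustable for c in conds]),
        life_qx=life_qx,
        prev_gp=surfaces.prevalence.values,
        discount_rate=params.discount_rate,
    )


def run_psa(params: ParameterSet, surfaces: ReferenceBundle,
            comparison: str = "bsci_vs_uc", n_iterations: int = 3000,
            seed: int | None = None, threshold: float | None = None,
            ceac_grid: np.ndarray | None = None,
            scenario: ScenarioConfig | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis for one comparison.

    Shared parameters are drawn once per iteration and applied to both
    arms (common random numbers); each arm's effectiveness is its own
    independent draw. Intervention costs carry no published uncertainty
    and stay fixed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if scenario is not None:
        params = apply_scenario(params, scenario)
    horizon = scenario.horizon if scenario is not None else None
    thr = params.threshold_gbp_per_qaly if threshold is None else threshold
    grid = (np.arange(0.0, 50_001.0, 1000.0)
            if ceac_grid is None else np.asarray(ceac_grid, dtype=float))
    rng = np.random.default_rng(seed)
    draws = sample_parameter_arrays(params, n_iterations, rng)

    arms = COMPARISONS[comparison]
    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    w = (surfaces.weights.w / surfaces.weights.w.sum()).reshape(-1)
    for arm in arms:
        inputs = _batch_inputs_from_draws(params, surfaces, arm, draws,
                                          n_iterations)
        result = run_batch(inputs, horizon=horizon)
        comorb = result.comorbidity_cost.reshape(n_iterations, -1) @ w
        qaly = result.qalys.reshape(n_iterations, -1) @ w
        costs[arm] = comorb + params.intervention_costs[arm].total
        qalys[arm] = qaly
    return PSAResult(
        comparison=comparison, arms=arms, costs=costs, qalys=qalys,
        threshold=thr, ceac_grid=grid, n_iterations=n_iterations, seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's low/high bound results in the tornado analysis."""

    parameter: str
    mean: float
    low: float
    high: float
    result_low: CEResult
    result_high: CEResult

    @property
    def icer_low(self) -> str:
        return self.result_low.icer_label

    @property
    def icer_high(self) -> str:
        return self.result_high.icer_label

    @property
    def nmb_range(self) -> float:
        """Width of the NMB swing; defined even under dominance labels."""
        return abs(self.result_high.nmb - self.result_low.nmb)


def _dsa_bounds(spec: DistributionSpec) -> tuple[float, float]:
    """95% interval bounds for one parameter, on its natural scale."""
    if spec.family == "degenerate":
        return spec.mean, spec.mean
    if spec.family == "lognormal":
        mu, s = spec.params["mu"], spec.params["sigma"]
        return float(np.exp(mu - 1.96 * s)), float(np.exp(mu + 1.96 * s))
    low = spec.mean - 1.96 * spec.sd
    high = spec.mean + 1.96 * spec.sd
    if spec.family == "beta":          # probabilities / utilities
        low, high = max(0.0, low), min(1.0, high)
    elif spec.family == "gamma":       # costs
        low = max(0.0, low)
    return low, high


def run_dsa(params: ParameterSet, surfaces: ReferenceBundle,
            comparison: str = "bsci_vs_uc",
            parameter_names: Sequence[str] | None = None,
            threshold: float | None = None,
            horizon: int | None = None) -> list[TornadoEntry]:
    """One-way tornado analysis: each parameter to its 95% bounds.

    Defaults to every parameter with a non-zero SD that enters this
    comparison (effectiveness of the two arms involved, plus all shared
    parameters). Effectiveness moves in its own arm only; shared
    parameters move in both arms simultaneously. Entries come back sorted
    by decreasing NMB range (the widest tornado bar first).
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    arms = set(COMPARISONS[comparison])
    specs = params.distribution_specs()
    if parameter_names is None:
        parameter_names = [
            name for name in sorted(specs)
            if specs[name].sd > 0
            and (not name.startswith("effectiveness:")
                 or name.split(":", 1)[1] in arms)
        ]
    entries = []
    for name in parameter_names:
        spec = specs[name]
        low, high = _dsa_bounds(spec)
        results = []
        for bound in (low, high):
            perturbed = _set_parameter(params, name, bound)
            results.append(evaluate_comparison(
                comparison, perturbed, surfaces, horizon=horizon,
                threshold=threshold))
        entries.append(TornadoEntry(name, spec.mean, low, high,
                                    results[0], results[1]))
    entries.sort(key=lambda e: e.nmb_range, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "mean": e.mean, "low": e.low, "high": e.high,
        "icer_low": e.icer_low, "icer_high": e.icer_high,
        "nmb_low": e.result_low.nmb, "nmb_high": e.result_high.nmb,
        "nmb_range": e.nmb_range,
    } for e in entries])
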