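"""Three-state annual-cycle Markov cohort: current smoker, former smoker, dead.

The cohort enters 100% in the current-smoker state. The intervention's
12-month quit probability drives the first current→former transition;
thereafter an annual net cessation rate (and, in one scenario, a relapse
rate) applies. Death competes first each cycle — the death probability d
comes from the age/sex/status life table scaled by the SMI relative
mortality risk, and smoking transitions apply conditional on survival,
(1-d)·q, which keeps rows stochastic without renormalisation. Costs and
QALYs accrue for the full year at each cycle's start-of-cycle occupancy
(no half-cycle correction); cycle 0 additionally accrues the
per-participant intervention cost. Both streams are discounted at
(1+r)^-t with cycle 0 undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .params import ParameterSet, TransitionRates, adjust_mortality
from .reference import (LifeTable, PrevalenceSurface, ReferenceBundle,
                        apply_smi_comorbidity_adjustment)

__all__ = [
    "STATES",
    "CohortTrace",
    "discount_factor",
    "build_transition_matrix",
    "state_utility",
    "state_cost",
    "run_cohort",
]

#: Health-state order used in every occupancy vector / transition matrix.
STATES = ("current_smoker", "former_smoker", "dead")
CURRENT, FORMER, DEAD = 0, 1, 2


def discount_factor(cycle_index: int, rate: float) -> float:
    """(1 + rate)^(-t); cycle 0 is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-cycle_index))


def build_transition_matrix(cycle_index: int, age: int, sex: str,
                            arm_quit_prob: float, rates: TransitionRates,
                            life_table: LifeTable,
                            rr_mortality: float) -> np.ndarray:
    """Row-stochastic 3x3 matrix for one cycle of one cohort.

    Cycle 0 uses the arm's 12-month quit probability for current→former;
    later cycles use the net cessation and relapse rates. Death competes
    first: current→former = (1-d)·q, so each row sums to exactly 1.
    """
    if cycle_index == 0:
        quit_p, relapse_p = arm_quit_prob, 0.0
    else:
        quit_p, relapse_p = rates.net_cessation[0], rates.relapse[0]
    for name, p in (("quit", quit_p), ("relapse", relapse_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} probability {p} outside [0, 1]")
    d_cur = adjust_mortality(life_table.q(age, sex, "current"), rr_mortality)
    d_fmr = adjust_mortality(life_table.q(age, sex, "former"), rr_mortality)
    return np.array([
        [(1 - d_cur) * (1 - quit_p), (1 - d_cur) * quit_p, d_cur],
        [(1 - d_fmr) * relapse_p, (1 - d_fmr) * (1 - relapse_p), d_fmr],
        [0.0, 0.0, 1.0],
    ])


def _smoking_status(state: int) -> str:
    return {CURRENT: "current", FORMER: "former"}[state]


def state_utility(state: int, age: int, sex: str, params: ParameterSet,
                  prevalence: PrevalenceSurface) -> float:
    """Annual utility of an alive state at an attained age.

    u = clamp(base - status decrement - SMI disutility
              - sum_c prev_c · (base - u_c), 0, 1).

    ``prevalence`` must already carry any SMI comorbidity adjustment.
    The dead state is handled by the caller as utility 0.
    """
    if state == DEAD:
        raise ValueError("dead state carries no utility; handled by caller")
    u = params.utilities
    base = u.base_nonsmoker[0]
    status_dec = {CURRENT: u.decrement_current[0],
                  FORMER: u.decrement_former[0]}[state]
    total = base - status_dec - u.smi_decrement[0]
    status = _smoking_status(state)
    for cond, cp in params.comorbidities.items():
        prev = float(prevalence.prevalence(cond, age, sex, status))
        total -= prev * (base - cp.utility_mean)
    return float(np.clip(total, 0.0, 1.0))


def state_cost(state: int, age: int, sex: str, params: ParameterSet,
               prevalence: PrevalenceSurface) -> float:
    """Annual comorbidity treatment cost of an alive state (GBP/cycle)."""
    if state == DEAD:
        raise ValueError("dead state carries no cost; handled by caller")
    status = _smoking_status(state)
    total = 0.0
    for cond, cp in params.comorbidities.items():
        total += float(prevalence.prevalence(cond, age, sex, status)) \
            * cp.annual_cost_mean
    return total


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one cohort run plus its lifetime totals.

    ``frame`` columns: cycle, age, occupancy per state, undiscounted and
    discounted cost (intervention + comorbidity split) and QALYs.
    """

    starting_age: int
    sex: str
    arm: str
    frame: pd.DataFrame

    @property
    def total_cost_discounted(self) -> float:
        return float(self.frame["cost_intervention_disc"].sum()
                     + self.frame["cost_comorbidity_disc"].sum())

    @property
    def total_cost_intervention(self) -> float:
        return float(self.frame["cost_intervention_disc"].sum())

    @property
    def total_cost_comorbidity(self) -> float:
        return float(self.frame["cost_comorbidity_disc"].sum())

    @property
    def total_qalys_discounted(self) -> float:
        return float(self.frame["qaly_disc"].sum())

    def occupancy(self) -> np.ndarray:
        return self.frame[["occ_current", "occ_former", "occ_dead"]].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_cohort(starting_age: int, sex: str, arm: str, params: ParameterSet,
               surfaces: ReferenceBundle, horizon: int | None = None,
               quit_prob: float | None = None,
               intervention_cost: float | None = None,
               prevalence_adjusted: PrevalenceSurface | None = None,
               ) -> CohortTrace:
    """Run one starting age / sex / arm through its remaining lifetime.

    ``horizon`` (years) truncates the run; by default the cohort is
    followed to the terminal age. ``quit_prob`` / ``intervention_cost``
    override the arm's table values (used by sensitivity analyses).
    ``prevalence_adjusted`` lets the caller reuse a precomputed
    SMI-adjusted surface; otherwise it is derived from the parameter set's
    comorbidity odds ratio (asthma exempt).
    """
    if not params.age_min <= starting_age <= params.age_max:
        raise ValueError(f"starting_age {starting_age} outside "
                         f"[{params.age_min}, {params.age_max}]")
    max_cycles = params.age_max - starting_age + 1
    if horizon is None:
        horizon = max_cycles
    if horizon < 1:
        raise ValueError("horizon must be >= 1 cycle")
    n_cycles = min(horizon, max_cycles)

    if quit_prob is None:
        quit_prob = params.effectiveness[arm].quit_prob_12m
    if intervention_cost is None:
        intervention_cost = params.intervention_costs[arm].total
    if prevalence_adjusted is None:
        exempt = {c for c, cp in params.comorbidities.items()
                  if not cp.smi_adjustable}
        prevalence_adjusted = apply_smi_comorbidity_adjustment(
            surfaces.prevalence, params.smi.or_comorbidity[0], exempt)

    rr = params.smi.rr_mortality[0]
    rate = params.discount_rate
    occ = np.array([1.0, 0.0, 0.0])
    rows = []
    for t in range(n_cycles):
        age = starting_age + t
        disc = discount_factor(t, rate)
        cost_com = sum(
            occ[s] * state_cost(s, age, sex, params, prevalence_adjusted)
            for s in (CURRENT, FORMER))
        qaly = sum(
            occ[s] * state_utility(s, age, sex, params, prevalence_adjusted)
            for s in (CURRENT, FORMER))
        cost_int = intervention_cost if t == 0 else 0.0
        rows.append({
            "cycle": t, "age": age,
            "occ_current": occ[CURRENT], "occ_former": occ[FORMER],
            "occ_dead": occ[DEAD],
            "cost_intervention": cost_int, "cost_comorbidity": cost_com,
            "qaly": qaly,
            "cost_intervention_disc": cost_int * disc,
            "cost_comorbidity_disc": cost_com * disc,
            "qaly_disc": qaly * disc,
        })
        matrix = build_transition_matrix(
            t, age, sex, quit_prob, params.transitions,
            surfaces.life_table, rr)
        occ = occ @ matrix
    return CohortTrace(starting_age, sex, arm, pd.DataFrame(rows))
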