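import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import smokece as sc
from smokece.params import ParameterSet
from smokece.reference import (N_AGES, PREV_STATUSES, SEXES, STATUSES,
                               LifeTable, PopulationWeights,
                               PrevalenceSurface, ReferenceBundle)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return sc.build_parameter_set()


@pytest.fixture(scope="session")
def surfaces() -> ReferenceBundle:
    return ReferenceBundle.generate(0)


@pytest.fixture(scope="session")
def model(params, surfaces) -> sc.CostEffectivenessModel:
    return sc.CostEffectivenessModel(params=params, surfaces=surfaces)


def zero_mortality_table() -> LifeTable:
    return LifeTable(np.zeros((N_AGES, len(SEXES), len(STATUSES))))


def certain_death_table() -> LifeTable:
    return LifeTable(np.ones((N_AGES, len(SEXES), len(STATUSES))))


def constant_prevalence(conditions, current=0.0, former=0.0,
                        overrides=None) -> PrevalenceSurface:
    """Age/sex-constant surface; ``overrides`` maps condition -> (cur, fmr)."""
    values = np.zeros((len(conditions), N_AGES, len(SEXES), len(PREV_STATUSES)))
    values[..., PREV_STATUSES.index("current")] = current
    values[..., PREV_STATUSES.index("former")] = former
    for cond, (cur, fmr) in (overrides or {}).items():
        ic = tuple(conditions).index(cond)
        values[ic, ..., PREV_STATUSES.index("current")] = cur
        values[ic, ..., PREV_STATUSES.index("former")] = fmr
    return PrevalenceSurface(tuple(conditions), values)


def uniform_weights() -> PopulationWeights:
    return PopulationWeights(np.full((N_AGES, len(SEXES)),
                                     1.0 / (N_AGES * len(SEXES))))


def degenerate(ps: ParameterSet) -> ParameterSet:
    """Copy of a parameter set with every SD forced to zero."""
    rep = dataclasses.replace
    zero2 = lambda pair: (pair[0], 0.0)
    return rep(
        ps,
        effectiveness={a: rep(e, sd=0.0) for a, e in ps.effectiveness.items()},
        comorbidities={c: rep(p, annual_cost_sd=0.0, utility_sd=0.0)
                       for c, p in ps.comorbidities.items()},
        utilities=rep(ps.utilities,
                      base_nonsmoker=zero2(ps.utilities.base_nonsmoker),
                      decrement_current=zero2(ps.utilities.decrement_current),
                      decrement_former=zero2(ps.utilities.decrement_former),
                      smi_decrement=zero2(ps.utilities.smi_decrement)),
        smi=rep(ps.smi,
                rr_mortality=zero2(ps.smi.rr_mortality),
                or_comorbidity=zero2(ps.smi.or_comorbidity),
                smi_disutility=zero2(ps.smi.smi_disutility)),
        transitions=rep(ps.transitions,
                        net_cessation=zero2(ps.transitions.net_cessation),
                        relapse=zero2(ps.transitions.relapse)),
    )
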