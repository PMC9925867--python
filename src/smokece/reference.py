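"""Synthetic reference surfaces: mortality, comorbidity prevalence, weights.

The cohort model consumes three external data surfaces that in practice
come from national statistics and epidemiological surveys: age/sex/
smoking-status all-cause mortality, age/sex/status prevalence of six
smoking-related comorbidities, and an age/sex population weighting used
to average lifetime results over starting ages 12–100. This module
generates synthetic stand-ins with the qualitative structure the model
assumes — mortality rising with age and ordered current >= former >=
never smoker, prevalence rising with age and higher for current than
former smokers, and a smooth unimodal population age profile. Surfaces
round-trip through long-format CSV so real reference data can be dropped
in without code changes.

Defaults were calibrated once so that population-weighted lifetime
discounted QALYs land near 11–12 per person, the order of magnitude of
published lifetime cost-utility results for this population, keeping
downstream directional checks meaningful. They are synthetic: no real
life table or survey was fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import or_to_rr

__all__ = [
    "SEXES",
    "STATUSES",
    "AGE_MIN",
    "AGE_MAX",
    "GompertzParams",
    "LogisticParams",
    "LifeTable",
    "PrevalenceSurface",
    "PopulationWeights",
    "ReferenceBundle",
    "generate_life_table",
    "generate_prevalence",
    "generate_population_weights",
    "apply_smi_comorbidity_adjustment",
]

SEXES = ("female", "male")
STATUSES = ("never", "current", "former")  # life-table smoking statuses
PREV_STATUSES = ("current", "former")      # prevalence is only needed for these
AGE_MIN, AGE_MAX = 12, 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size  # 89


# ---------------------------------------------------------------------------
# parameter shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GompertzParams:
    """Gompertz mortality q(age) = a * exp(b * age), times a status multiplier.

    ``a`` is sex-specific; multipliers must be ordered
    current >= former >= never so the status ordering invariant holds
    (equality is allowed, collapsing the status curves onto each other).
    """

    a: Mapping[str, float] = field(
        default_factory=lambda: {"female": 8.0e-6, "male": 1.2e-5})
    b: float = 0.095
    multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"never": 1.0, "former": 1.3, "current": 2.0})


@dataclass(frozen=True)
class LogisticParams:
    """Logistic-in-age prevalence for one condition (current smokers).

    prev(age) = asymptote * sex_factor / (1 + exp(-slope * (age - midpoint)));
    former smokers get the same curve attenuated by ``former_attenuation``
    in (0, 1].
    """

    asymptote: float
    midpoint: float
    slope: float
    former_attenuation: float


#: Default prevalence shapes per condition. Asymptotes/midpoints are
#: synthetic but ordered sensibly: COPD/CHD common in old age, lung
#: cancer rare, asthma flatter in age and barely smoking-status dependent.
DEFAULT_PREVALENCE_PARAMS: dict[str, LogisticParams] = {
    "asthma": LogisticParams(0.13, 37.0, 0.05, 0.90),
    "copd": LogisticParams(0.39, 72.0, 0.09, 0.50),
    "chd": LogisticParams(0.325, 72.0, 0.08, 0.70),
    "lung_cancer": LogisticParams(0.052, 77.0, 0.09, 0.50),
    "mi": LogisticParams(0.26, 75.0, 0.08, 0.70),
    "stroke": LogisticParams(0.195, 77.0, 0.08, 0.70),
}

_SEX_FACTOR = {"female": 0.9, "male": 1.1}


# ---------------------------------------------------------------------------
# surface containers
# ---------------------------------------------------------------------------

def _age_index(age) -> np.ndarray | int:
    idx = np.asarray(age) - AGE_MIN
    if np.any(idx < 0) or np.any(idx >= N_AGES):
        raise KeyError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    return idx


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability on an age x sex x smoking-status grid."""

    qx: np.ndarray  # (n_ages, 2 sexes, 3 statuses)

    def q(self, age, sex: str, status: str):
        return self.qx[_age_index(age), SEXES.index(sex), STATUSES.index(status)]

    def validate(self) -> "LifeTable":
        if self.qx.shape != (N_AGES, len(SEXES), len(STATUSES)):
            raise ValueError(f"life table shape {self.qx.shape} invalid")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValueError("death probabilities outside [0, 1]")
        if np.any(np.diff(self.qx, axis=0) < -1e-12):
            raise ValueError("death probability decreases with age")
        cur, fmr, nev = (self.qx[..., STATUSES.index(s)]
                         for s in ("current", "former", "never"))
        if np.any(cur < fmr - 1e-12) or np.any(fmr < nev - 1e-12):
            raise ValueError("status ordering current >= former >= never violated")
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(a), s, st, float(self.qx[i, j, k]))
                for i, a in enumerate(AGES)
                for j, s in enumerate(SEXES)
                for k, st in enumerate(STATUSES)]
        return pd.DataFrame(rows, columns=["age", "sex", "status", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        qx = np.full((N_AGES, len(SEXES), len(STATUSES)), np.nan)
        for r in frame.itertuples():
            qx[int(r.age) - AGE_MIN, SEXES.index(r.sex), STATUSES.index(r.status)] = r.value
        if np.isnan(qx).any():
            raise ValueError("life-table frame does not cover the full grid")
        return cls(qx).validate()


@dataclass(frozen=True)
class PrevalenceSurface:
    """Comorbidity prevalence per condition x age x sex x smoking status."""

    conditions: tuple[str, ...]
    values: np.ndarray  # (n_cond, n_ages, 2 sexes, 2 statuses: current, former)

    def prevalence(self, condition: str, age, sex: str, status: str):
        return self.values[self.conditions.index(condition), _age_index(age),
                           SEXES.index(sex), PREV_STATUSES.index(status)]

    def validate(self) -> "PrevalenceSurface":
        if self.values.shape != (len(self.conditions), N_AGES, len(SEXES),
                                 len(PREV_STATUSES)):
            raise ValueError(f"prevalence shape {self.values.shape} invalid")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("prevalence outside [0, 1]")
        if np.any(np.diff(self.values, axis=1) < -1e-12):
            raise ValueError("prevalence decreases with age")
        cur = self.values[..., PREV_STATUSES.index("current")]
        fmr = self.values[..., PREV_STATUSES.index("former")]
        if np.any(cur < fmr - 1e-12):
            raise ValueError("current-smoker prevalence below former-smoker")
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, int(a), s, st, float(self.values[ic, ia, js, kt]))
                for ic, c in enumerate(self.conditions)
                for ia, a in enumerate(AGES)
                for js, s in enumerate(SEXES)
                for kt, st in enumerate(PREV_STATUSES)]
        return pd.DataFrame(rows, columns=["condition", "age", "sex", "status", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PrevalenceSurface":
        conditions = tuple(dict.fromkeys(frame["condition"]))
        values = np.full((len(conditions), N_AGES, len(SEXES), len(PREV_STATUSES)),
                         np.nan)
        for r in frame.itertuples():
            values[conditions.index(r.condition), int(r.age) - AGE_MIN,
                   SEXES.index(r.sex), PREV_STATUSES.index(r.status)] = r.value
        if np.isnan(values).any():
            raise ValueError("prevalence frame does not cover the full grid")
        return cls(conditions, values).validate()


@dataclass(frozen=True)
class PopulationWeights:
    """Normalised weight per (age, sex) cell used to average lifetime results."""

    w: np.ndarray  # (n_ages, 2 sexes), sums to 1

    def weight(self, age, sex: str):
        return self.w[_age_index(age), SEXES.index(sex)]

    def validate(self) -> "PopulationWeights":
        if self.w.shape != (N_AGES, len(SEXES)):
            raise ValueError(f"weights shape {self.w.shape} invalid")
        if np.any(self.w < 0):
            raise ValueError("negative population weight")
        if abs(float(self.w.sum()) - 1.0) > 1e-12:
            raise ValueError("population weights do not sum to 1")
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(a), s, float(self.w[i, j]))
                for i, a in enumerate(AGES) for j, s in enumerate(SEXES)]
        return pd.DataFrame(rows, columns=["age", "sex", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationWeights":
        w = np.full((N_AGES, len(SEXES)), np.nan)
        for r in frame.itertuples():
            w[int(r.age) - AGE_MIN, SEXES.index(r.sex)] = r.value
        if np.isnan(w).any():
            raise ValueError("weights frame does not cover the full grid")
        return cls(w).validate()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_life_table(seed: int = 0, params: GompertzParams | None = None,
                        jitter: float = 0.03) -> LifeTable:
    """Gompertz life table; the seed perturbs (a, b) within ±``jitter``.

    q(age, sex, status) = min(1, a_sex * exp(b * age)) * multiplier_status,
    clipped to [0, 1], with q forced to 1 at the terminal age 100 so the
    final model cycle is absorbing-by-death. Bit-identical for a fixed
    seed.
    """
    params = params or GompertzParams()
    m = params.multipliers
    if not m["current"] >= m["former"] >= m["never"]:
        raise ValueError("status multipliers must satisfy current >= former >= never")
    rng = np.random.default_rng(seed)
    qx = np.empty((N_AGES, len(SEXES), len(STATUSES)))
    for j, sex in enumerate(SEXES):
        a = params.a[sex] * (1.0 + rng.uniform(-jitter, jitter))
        b = params.b * (1.0 + rng.uniform(-jitter, jitter))
        base = np.minimum(1.0, a * np.exp(b * AGES))
        for k, status in enumerate(STATUSES):
            qx[:, j, k] = np.minimum(1.0, base * m[status])
    qx[-1, :, :] = 1.0  # age 100 is absorbing-by-death
    return LifeTable(qx).validate()


def generate_prevalence(seed: int = 0,
                        params: Mapping[str, LogisticParams] | None = None,
                        jitter: float = 0.05,
                        sex_factor: Mapping[str, float] | None = None,
                        ) -> PrevalenceSurface:
    """General-population prevalence surfaces (before any SMI adjustment).

    Logistic-in-age per condition, former-smoker curves attenuated by a
    factor in (0, 1]; the seed perturbs each asymptote within ±``jitter``.
    """
    params = dict(params or DEFAULT_PREVALENCE_PARAMS)
    sex_factor = dict(sex_factor or _SEX_FACTOR)
    rng = np.random.default_rng(seed)
    conditions = tuple(params)
    values = np.empty((len(conditions), N_AGES, len(SEXES), len(PREV_STATUSES)))
    for ic, cond in enumerate(conditions):
        p = params[cond]
        if not 0.0 < p.former_attenuation <= 1.0:
            raise ValueError(f"{cond}: former_attenuation must be in (0, 1]")
        if p.asymptote > 1.0:
            raise ValueError(f"{cond}: asymptote must be <= 1")
        asym = p.asymptote * (1.0 + rng.uniform(-jitter, jitter))
        curve = 1.0 / (1.0 + np.exp(-p.slope * (AGES - p.midpoint)))
        for js, sex in enumerate(SEXES):
            cur = np.clip(asym * sex_factor[sex], 0.0, 1.0) * curve
            values[ic, :, js, PREV_STATUSES.index("current")] = cur
            values[ic, :, js, PREV_STATUSES.index("former")] = (
                cur * p.former_attenuation)
    return PrevalenceSurface(conditions, values).validate()


def generate_population_weights(seed: int = 0, mean_age: float = 40.0,
                                sd_age: float = 22.0, sex_split: float = 0.5,
                                uniform: bool = False,
                                jitter: float = 0.03) -> PopulationWeights:
    """Smooth unimodal age profile split by sex, normalised to sum 1.

    ``uniform=True`` gives equal mass on every (age, sex) cell. The seed
    perturbs the profile's mean and spread within ±``jitter``.
    """
    if uniform:
        w = np.full((N_AGES, len(SEXES)), 1.0 / (N_AGES * len(SEXES)))
        return PopulationWeights(w).validate()
    rng = np.random.default_rng(seed)
    mu = mean_age * (1.0 + rng.uniform(-jitter, jitter))
    sd = sd_age * (1.0 + rng.uniform(-jitter, jitter))
    profile = np.exp(-0.5 * ((AGES - mu) / sd) ** 2)
    w = np.stack([profile * (1.0 - sex_split), profile * sex_split], axis=1)
    w = w / w.sum()
    return PopulationWeights(w).validate()


def apply_smi_comorbidity_adjustment(
        surface: PrevalenceSurface, or_comorbidity: float,
        exempt: Iterable[str] = ("asthma",)) -> PrevalenceSurface:
    """Uplift prevalence for the SMI population via the comorbidity OR.

    For each non-exempt cell with general-population prevalence p the
    adjusted value is min(1, p * RR) with RR = or_to_rr(OR, p), i.e. the
    odds ratio is converted to a prevalence-specific relative risk before
    it multiplies the prevalence. Exempt conditions (asthma, whose
    exacerbations match general-population rates) are unchanged.
    """
    exempt = set(exempt)
    values = surface.values.copy()
    for ic, cond in enumerate(surface.conditions):
        if cond in exempt:
            continue
        p = values[ic]
        values[ic] = np.minimum(1.0, p * or_to_rr(or_comorbidity, p))
    return PrevalenceSurface(surface.conditions, values).validate()


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceBundle:
    """The three reference surfaces a model run needs, generated or loaded."""

    life_table: LifeTable
    prevalence: PrevalenceSurface  # general-population (pre-SMI-adjustment)
    weights: PopulationWeights
    seed: int | None = None

    @classmethod
    def generate(cls, seed: int = 0, **kwargs) -> "ReferenceBundle":
        return cls(
            life_table=generate_life_table(seed, **kwargs.get("life_table", {})),
            prevalence=generate_prevalence(seed, **kwargs.get("prevalence", {})),
            weights=generate_population_weights(seed, **kwargs.get("weights", {})),
            seed=seed,
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.life_table.to_frame().to_csv(directory / "life_table.csv", index=False)
        self.prevalence.to_frame().to_csv(directory / "prevalence.csv", index=False)
        self.weights.to_frame().to_csv(directory / "population_weights.csv",
                                       index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceBundle":
        directory = Path(directory)
        return cls(
            life_table=LifeTable.from_frame(
                pd.read_csv(directory / "life_table.csv")),
            prevalence=PrevalenceSurface.from_frame(
                pd.read_csv(directory / "prevalence.csv")),
            weights=PopulationWeights.from_frame(
                pd.read_csv(directory / "population_weights.csv")),
        )
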