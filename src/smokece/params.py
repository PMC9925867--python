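"""Model inputs: effectiveness, costs, utilities, epidemiological adjustments.

Houses every input of the cost-utility model — arm-level 12-month quit
probabilities, per-participant intervention costs (GBP 2018/19), annual
comorbidity treatment costs and utilities, transition rates, and the
adjustments specific to populations with severe mental illness (SMI):
a relative mortality risk, an odds ratio for smoking-related comorbidity,
and a health-state disutility. Also provides the odds-ratio to
relative-risk conversion, the population-weighted SMI disutility, and
moment-matched sampling distributions for probabilistic sensitivity
analysis (PSA).

All monetary values are GBP 2018/19; utilities are on the 0–1 EQ-5D-style
scale; probabilities are annual unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "COMPARISONS",
    "CONDITIONS",
    "EffectivenessEstimate",
    "InterventionCost",
    "ComorbidityParameter",
    "SmiAdjustments",
    "DisutilityComponents",
    "UtilityParameters",
    "TransitionRates",
    "DistributionSpec",
    "ParameterSet",
    "ParameterValidationError",
    "or_to_rr",
    "weighted_disutility",
    "adjust_mortality",
    "moment_match",
    "build_parameter_set",
]

#: Intervention arms. BSCI = bespoke smoking-cessation intervention
#: (vs usual care); integrated care = tobacco cessation integrated with
#: mental-health care (vs referral to a smoking-cessation clinic, SCC).
ARMS = ("bsci", "usual_care", "integrated_care", "scc_referral")

#: The two pairwise comparisons evaluated: (intervention, comparator).
COMPARISONS = {
    "bsci_vs_uc": ("bsci", "usual_care"),
    "ic_vs_scc": ("integrated_care", "scc_referral"),
}

#: Smoking-related comorbidities carrying costs and disutilities.
CONDITIONS = ("asthma", "copd", "chd", "lung_cancer", "mi", "stroke")

#: Printed intervention-cost totals may differ from component sums by a
#: few pounds (rounding in the source tables); totals are canonical.
COST_TOTAL_TOLERANCE_GBP = 7.0


class ParameterValidationError(ValueError):
    """Raised with the full list of offending entries, not just the first."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid parameters:\n  - " + "\n  - ".join(self.problems))


# ---------------------------------------------------------------------------
# derived-quantity operations
# ---------------------------------------------------------------------------

def or_to_rr(odds_ratio, baseline_prob):
    """Convert an odds ratio to a relative risk at a baseline probability.

    RR = OR / (1 - p + p * OR), where ``p`` is the outcome probability in
    the unexposed (general) population. Accepts scalars or arrays. The
    result always lies between ``min(1, OR)`` and ``max(1, OR)``.
    """
    or_arr = np.asarray(odds_ratio, dtype=float)
    p = np.asarray(baseline_prob, dtype=float)
    if np.any(or_arr <= 0):
        raise ValueError("odds_ratio must be positive")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("baseline_prob must lie in [0, 1)")
    out = or_arr / (1.0 - p + p * or_arr)
    if out.ndim == 0:
        return float(out)
    return out


def weighted_disutility(components: "DisutilityComponents") -> float:
    """Population-weighted average disutility across mental-health conditions.

    Weights are normalised internally, so any positive rescaling of the
    inputs gives the same answer. Returns the decrement magnitude.
    """
    return components.weighted_mean()


def adjust_mortality(base_annual_prob, rr):
    """Scale an annual death probability by a relative risk, capped at 1."""
    q = np.asarray(base_annual_prob, dtype=float)
    r = np.asarray(rr, dtype=float)
    if np.any(q < 0) or np.any(r < 0):
        raise ValueError("mortality probability and relative risk must be >= 0")
    out = np.minimum(1.0, q * r)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# PSA sampling distributions
# ---------------------------------------------------------------------------

_FAMILIES = ("lognormal", "beta", "gamma", "degenerate")


@dataclass(frozen=True)
class DistributionSpec:
    """A moment-matched sampling distribution for one model parameter.

    ``mean`` and ``sd`` are on the parameter's natural (magnitude) scale;
    ``sign`` is -1 for utility decrements that the source tables print as
    negative values — the magnitude is sampled from a beta distribution
    (support [0, 1]) and the sign is applied downstream when the decrement
    is subtracted.
    """

    family: str
    mean: float
    sd: float
    params: Mapping[str, float]
    sign: int = 1
    name: str = ""

    def sample(self, rng: np.random.Generator, size=None):
        """Draw magnitude(s); the caller applies ``sign`` where relevant."""
        if self.family == "degenerate":
            return np.full(size, self.mean) if size is not None else self.mean
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size)
        raise ValueError(f"unknown family {self.family!r}")

    def closed_form_moments(self) -> tuple[float, float]:
        """(mean, sd) implied by the fitted shape parameters."""
        if self.family == "degenerate":
            return self.mean, 0.0
        if self.family == "gamma":
            k, th = self.params["shape"], self.params["scale"]
            return k * th, math.sqrt(k) * th
        if self.family == "lognormal":
            mu, s = self.params["mu"], self.params["sigma"]
            m = math.exp(mu + s * s / 2.0)
            return m, m * math.sqrt(math.expm1(s * s))
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1.0))
            return m, math.sqrt(v)
        raise ValueError(f"unknown family {self.family!r}")


def moment_match(family: str, mean: float, sd: float, *, sign: int = 1,
                 name: str = "") -> DistributionSpec:
    """Fit a distribution of the given family to a (mean, SD) pair.

    Method-of-moments inversion: gamma shape = mean^2/sd^2 and scale =
    sd^2/mean; lognormal sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) -
    sigma^2/2; beta nu = mean(1-mean)/sd^2 - 1 with alpha = mean*nu.
    ``sd == 0`` yields a degenerate point mass for any family.
    """
    label = name or family
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if sd < 0:
        raise ValueError(f"{label}: sd must be >= 0")
    if sd == 0 or family == "degenerate":
        return DistributionSpec("degenerate", mean, 0.0, {}, sign, name)
    if mean <= 0 and family in ("gamma", "lognormal"):
        raise ValueError(f"{label}: {family} requires mean > 0")
    if family == "gamma":
        params = {"shape": mean**2 / sd**2, "scale": sd**2 / mean}
    elif family == "lognormal":
        sigma2 = math.log1p(sd**2 / mean**2)
        params = {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    else:  # beta
        if not 0.0 < mean < 1.0:
            raise ValueError(f"{label}: beta requires 0 < mean < 1")
        if sd**2 >= mean * (1.0 - mean):
            raise ValueError(
                f"{label}: beta infeasible, sd^2 = {sd**2:.6g} >= "
                f"mean*(1-mean) = {mean * (1.0 - mean):.6g}"
            )
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        params = {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
    return DistributionSpec(family, mean, sd, params, sign, name)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectivenessEstimate:
    """Biochemically validated 12-month abstinence probability for one arm."""

    arm_name: str
    quit_prob_12m: float
    sd: float

    def problems(self) -> list[str]:
        out = []
        if not 0.0 <= self.quit_prob_12m <= 1.0:
            out.append(f"effectiveness[{self.arm_name}]: quit_prob_12m "
                       f"{self.quit_prob_12m} outside [0, 1]")
        if self.sd < 0:
            out.append(f"effectiveness[{self.arm_name}]: negative sd")
        return out


@dataclass(frozen=True)
class InterventionCost:
    """Per-participant intervention cost components and printed total (GBP)."""

    arm_name: str
    components: Mapping[str, float]
    total: float

    def problems(self) -> list[str]:
        out = []
        for label, value in self.components.items():
            if value < 0:
                out.append(f"intervention_cost[{self.arm_name}:{label}]: negative")
        if self.total < 0:
            out.append(f"intervention_cost[{self.arm_name}]: negative total")
        gap = abs(self.total - sum(self.components.values()))
        if gap > COST_TOTAL_TOLERANCE_GBP:
            out.append(
                f"intervention_cost[{self.arm_name}]: total {self.total} differs "
                f"from component sum by {gap:.2f} > {COST_TOTAL_TOLERANCE_GBP}"
            )
        return out


@dataclass(frozen=True)
class ComorbidityParameter:
    """Annual treatment cost and health-state utility for one comorbidity.

    ``smi_adjustable`` is False for asthma: its exacerbation rates are
    taken as equal to general-population rates, so the comorbidity odds
    ratio is never applied to it.
    """

    condition: str
    annual_cost_mean: float
    annual_cost_sd: float
    utility_mean: float
    utility_sd: float
    smi_adjustable: bool = True

    def problems(self) -> list[str]:
        out = []
        if self.condition not in CONDITIONS:
            out.append(f"comorbidity[{self.condition}]: unknown condition")
        if self.annual_cost_mean < 0 or self.annual_cost_sd < 0:
            out.append(f"comorbidity[{self.condition}]: negative cost")
        if not 0.0 <= self.utility_mean <= 1.0:
            out.append(f"comorbidity[{self.condition}]: utility outside [0, 1]")
        if self.condition == "asthma" and self.smi_adjustable:
            out.append("comorbidity[asthma]: must not be SMI-adjustable")
        return out


@dataclass(frozen=True)
class SmiAdjustments:
    """SMI-specific epidemiology: mortality RR, comorbidity OR, disutility.

    Each entry is a (mean, sd) pair. The relative mortality risk
    multiplies age/sex/status-specific death probabilities; the odds ratio
    is converted to prevalence-specific relative risks via `or_to_rr`; the
    disutility is subtracted from every alive state's utility.
    """

    rr_mortality: tuple[float, float] = (2.22, 0.02)
    or_comorbidity: tuple[float, float] = (3.10, 0.29)
    smi_disutility: tuple[float, float] = (0.125, 0.013)

    def problems(self) -> list[str]:
        out = []
        if self.rr_mortality[0] <= 0:
            out.append("smi.rr_mortality: must be > 0")
        if self.or_comorbidity[0] <= 0:
            out.append("smi.or_comorbidity: must be > 0")
        if not 0.0 <= self.smi_disutility[0] <= 1.0:
            out.append("smi.smi_disutility: outside [0, 1]")
        return out


@dataclass(frozen=True)
class DisutilityComponents:
    """Condition-specific disutilities with population weights.

    The SMI disutility applied in the model is the weighted average of
    mental-health-condition-specific decrements (mood disorder, anxiety
    disorder, substance misuse disorder).
    """

    components: tuple[tuple[str, float, float], ...]  # (label, disutility, weight)

    def weighted_mean(self) -> float:
        if not self.components:
            raise ValueError("no disutility components supplied")
        w = np.array([c[2] for c in self.components], dtype=float)
        d = np.array([c[1] for c in self.components], dtype=float)
        if np.any(w < 0):
            raise ValueError("disutility weights must be >= 0")
        total = w.sum()
        if total <= 0:
            raise ValueError("disutility weights sum to zero")
        return float((w / total) @ d)

    def problems(self) -> list[str]:
        out = []
        for label, d, w in self.components:
            if not 0.0 <= d <= 1.0:
                out.append(f"disutility[{label}]: magnitude outside [0, 1]")
            if w < 0:
                out.append(f"disutility[{label}]: negative weight")
        return out


@dataclass(frozen=True)
class UtilityParameters:
    """Smoking-status utility model: base value and additive decrements.

    State utility before comorbidity adjustment is
    ``base_nonsmoker - status decrement - smi_decrement``, all on the 0–1
    scale; decrements are stored as positive magnitudes.
    """

    base_nonsmoker: tuple[float, float] = (0.88, 0.13)
    decrement_current: tuple[float, float] = (0.04, 0.01)
    decrement_former: tuple[float, float] = (0.02, 0.01)
    smi_decrement: tuple[float, float] = (0.125, 0.013)

    def problems(self) -> list[str]:
        out = []
        if not 0.0 <= self.base_nonsmoker[0] <= 1.0:
            out.append("utilities.base_nonsmoker: outside [0, 1]")
        for nm in ("decrement_current", "decrement_former", "smi_decrement"):
            if getattr(self, nm)[0] < 0:
                out.append(f"utilities.{nm}: negative decrement")
        return out


@dataclass(frozen=True)
class TransitionRates:
    """Post-12-month annual transition probabilities.

    ``net_cessation`` is a *net* quit rate absorbing quitting, failed quit
    attempts and relapse at the population level (base case 2%/year);
    ``relapse`` is therefore 0 in the base case and only non-zero in the
    scenario that models the two flows separately.
    """

    net_cessation: tuple[float, float] = (0.02, 0.003)
    relapse: tuple[float, float] = (0.0, 0.0)

    def problems(self) -> list[str]:
        out = []
        for nm in ("net_cessation", "relapse"):
            if not 0.0 <= getattr(self, nm)[0] <= 1.0:
                out.append(f"transitions.{nm}: outside [0, 1]")
        return out


@dataclass(frozen=True)
class ParameterSet:
    """Every input of one model run; the single source of truth.

    Derived quantities (the weighted SMI disutility, the PSA distribution
    specs) are computed from, never stored alongside, the raw entries.
    """

    effectiveness: Mapping[str, EffectivenessEstimate]
    intervention_costs: Mapping[str, InterventionCost]
    comorbidities: Mapping[str, ComorbidityParameter]
    utilities: UtilityParameters
    smi: SmiAdjustments
    transitions: TransitionRates
    disutility_components: DisutilityComponents
    service_utilisation: Mapping[str, float] = field(default_factory=dict)
    self_report_effectiveness: Mapping[str, EffectivenessEstimate] | None = None
    discount_rate: float = 0.035
    threshold_gbp_per_qaly: float = 20_000.0
    age_min: int = 12
    age_max: int = 100

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ParameterSet":
        problems: list[str] = []
        for arm in ARMS:
            if arm not in self.effectiveness:
                problems.append(f"effectiveness: missing arm {arm!r}")
            if arm not in self.intervention_costs:
                problems.append(f"intervention_costs: missing arm {arm!r}")
        for cond in CONDITIONS:
            if cond not in self.comorbidities:
                problems.append(f"comorbidities: missing condition {cond!r}")
        for group in (*self.effectiveness.values(),
                      *self.intervention_costs.values(),
                      *self.comorbidities.values(),
                      self.utilities, self.smi, self.transitions,
                      self.disutility_components):
            problems.extend(group.problems())
        if self.discount_rate < 0:
            problems.append("discount_rate: must be >= 0")
        if self.threshold_gbp_per_qaly <= 0:
            problems.append("threshold_gbp_per_qaly: must be > 0")
        if not self.age_min < self.age_max:
            problems.append("age range: age_min must be < age_max")
        if problems:
            raise ParameterValidationError(problems)
        return self

    # -- derived ------------------------------------------------------------
    @property
    def smi_disutility_mean(self) -> float:
        return self.smi.smi_disutility[0]

    def distribution_specs(self) -> dict[str, DistributionSpec]:
        """Moment-matched PSA distributions, keyed by parameter name.

        Families follow the usual health-economics conventions: lognormal
        for relative risks / odds ratios, beta for probabilities and
        utilities (decrements on magnitude with sign -1), gamma for costs.
        Intervention costs carry no published uncertainty and are fixed.
        """
        specs: dict[str, DistributionSpec] = {}

        def put(name, family, mean, sd, sign=1):
            specs[name] = moment_match(family, mean, sd, sign=sign, name=name)

        for arm, eff in self.effectiveness.items():
            put(f"effectiveness:{arm}", "beta", eff.quit_prob_12m, eff.sd)
        for cond, cp in self.comorbidities.items():
            put(f"cost:{cond}", "gamma", cp.annual_cost_mean, cp.annual_cost_sd)
            put(f"utility:{cond}", "beta", cp.utility_mean, cp.utility_sd)
        u = self.utilities
        put("utility:base_nonsmoker", "beta", *u.base_nonsmoker)
        put("decrement:current", "beta", *u.decrement_current, sign=-1)
        put("decrement:former", "beta", *u.decrement_former, sign=-1)
        put("decrement:smi", "beta", *self.smi.smi_disutility, sign=-1)
        put("rr_mortality", "lognormal", *self.smi.rr_mortality)
        put("or_comorbidity", "lognormal", *self.smi.or_comorbidity)
        put("transition:net_cessation", "beta", *self.transitions.net_cessation)
        put("transition:relapse", "beta", *self.transitions.relapse)
        return specs

    # -- convenience modifiers (return new sets) ----------------------------
    def with_transitions(self, net_cessation: float, relapse: float) -> "ParameterSet":
        tr = TransitionRates((net_cessation, self.transitions.net_cessation[1]),
                             (relapse, self.transitions.relapse[1]))
        return replace(self, transitions=tr)

    def with_effectiveness(self, values: Mapping[str, float]) -> "ParameterSet":
        eff = dict(self.effectiveness)
        for arm, p in values.items():
            eff[arm] = replace(eff[arm], quit_prob_12m=p)
        return replace(self, effectiveness=eff)

    def with_self_report_effectiveness(self) -> "ParameterSet":
        if not self.self_report_effectiveness:
            raise ValueError(
                "self-reported effectiveness inputs are not configured"
            )
        return replace(self, effectiveness=dict(self.self_report_effectiveness))

    def with_service_utilisation_costs(self) -> "ParameterSet":
        """Fold the 12-month service-utilisation add-on into arm costs."""
        costs = {}
        for arm, ic in self.intervention_costs.items():
            addon = float(self.service_utilisation.get(arm, 0.0))
            comps = dict(ic.components)
            comps["service_utilisation"] = addon
            # the printed-total tolerance applies to the table entries, not
            # to the scenario arithmetic, so keep total exactly consistent
            costs[arm] = InterventionCost(arm, comps, ic.total + addon)
        return replace(self, intervention_costs=costs)


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

def _data_path() -> Path:
    return Path(resources.files("smokece").joinpath("data"))


def _read_csv(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise FileNotFoundError(f"missing parameter table {path}")
    return pd.read_csv(path)


def build_parameter_set(directory: str | Path | None = None, *,
                        discount_rate: float = 0.035,
                        threshold_gbp_per_qaly: float = 20_000.0) -> ParameterSet:
    """Assemble and validate a ParameterSet from CSV tables.

    With no arguments the tables shipped with the package (transcriptions
    of the published input tables, plus clearly-labelled synthetic
    placeholders for the self-reported effectiveness inputs) are used.
    Raises :class:`ParameterValidationError` listing every offending row
    if anything is missing, duplicated or out of range.
    """
    directory = Path(directory) if directory is not None else _data_path()
    problems: list[str] = []

    eff_df = _read_csv(directory, "effectiveness.csv")
    if eff_df["arm"].duplicated().any():
        dupes = sorted(eff_df.loc[eff_df["arm"].duplicated(), "arm"])
        problems.append(f"effectiveness.csv: duplicate arms {dupes}")
    effectiveness = {
        r.arm: EffectivenessEstimate(r.arm, float(r.quit_prob_12m), float(r.sd))
        for r in eff_df.itertuples()
    }

    cost_df = _read_csv(directory, "intervention_costs.csv")
    intervention_costs = {}
    for arm, grp in cost_df.groupby("arm"):
        comps = {r.component: float(r.gbp) for r in grp.itertuples()
                 if r.component != "total_printed"}
        tot = grp.loc[grp["component"] == "total_printed", "gbp"]
        if tot.empty:
            problems.append(f"intervention_costs.csv[{arm}]: missing total_printed")
            total = sum(comps.values())
        else:
            total = float(tot.iloc[0])
        intervention_costs[arm] = InterventionCost(arm, comps, total)

    com_df = _read_csv(directory, "comorbidities.csv")
    comorbidities = {}
    for r in com_df.itertuples():
        adjustable = str(r.smi_adjustable).strip().lower() in ("true", "1", "yes")
        comorbidities[r.condition] = ComorbidityParameter(
            r.condition, float(r.annual_cost_mean), float(r.annual_cost_sd),
            float(r.utility_mean), float(r.utility_sd), adjustable,
        )

    util_df = _read_csv(directory, "utilities.csv").set_index("parameter")

    def pair(frame, key, table):
        try:
            row = frame.loc[key]
        except KeyError:
            problems.append(f"{table}: missing parameter {key!r}")
            return (math.nan, math.nan)
        return (float(row["mean"]), float(row["sd"]))

    utilities = UtilityParameters(
        base_nonsmoker=pair(util_df, "base_nonsmoker", "utilities.csv"),
        decrement_current=pair(util_df, "decrement_current", "utilities.csv"),
        decrement_former=pair(util_df, "decrement_former", "utilities.csv"),
        smi_decrement=pair(util_df, "smi_decrement", "utilities.csv"),
    )

    smi_df = _read_csv(directory, "smi_adjustments.csv").set_index("parameter")
    smi = SmiAdjustments(
        rr_mortality=pair(smi_df, "rr_mortality", "smi_adjustments.csv"),
        or_comorbidity=pair(smi_df, "or_comorbidity", "smi_adjustments.csv"),
        smi_disutility=pair(smi_df, "smi_disutility", "smi_adjustments.csv"),
    )

    tr_df = _read_csv(directory, "transitions.csv").set_index("parameter")
    transitions = TransitionRates(
        net_cessation=pair(tr_df, "net_cessation", "transitions.csv"),
        relapse=pair(tr_df, "relapse", "transitions.csv"),
    )

    dis_df = _read_csv(directory, "disutility_components.csv")
    disutility = DisutilityComponents(tuple(
        (r.condition, float(r.disutility), float(r.weight))
        for r in dis_df.itertuples()
    ))

    su_df = _read_csv(directory, "service_utilisation.csv")
    service_utilisation = {r.arm: float(r.gbp) for r in su_df.itertuples()}

    self_report = None
    sr_path = directory / "self_report_effectiveness_synthetic.csv"
    if sr_path.exists():
        sr_df = pd.read_csv(sr_path)
        self_report = {
            r.arm: EffectivenessEstimate(r.arm, float(r.quit_prob_12m), float(r.sd))
            for r in sr_df.itertuples()
        }

    if problems:
        raise ParameterValidationError(problems)

    ps = ParameterSet(
        effectiveness=effectiveness,
        intervention_costs=intervention_costs,
        comorbidities=comorbidities,
        utilities=utilities,
        smi=smi,
        transitions=transitions,
        disutility_components=disutility,
        service_utilisation=service_utilisation,
        self_report_effectiveness=self_report,
        discount_rate=discount_rate,
        threshold_gbp_per_qaly=threshold_gbp_per_qaly,
    )
    return ps.validate()


def parameter_set_to_json(ps: ParameterSet) -> str:
    """Serialise a ParameterSet to the merged JSON interchange form."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))
    payload = {
        "effectiveness": {a: dataclasses.asdict(e) for a, e in ps.effectiveness.items()},
        "intervention_costs": {a: {"components": dict(c.components), "total": c.total}
                               for a, c in ps.intervention_costs.items()},
        "comorbidities": {c: dataclasses.asdict(p) for c, p in ps.comorbidities.items()},
        "utilities": dataclasses.asdict(ps.utilities),
        "smi": dataclasses.asdict(ps.smi),
        "transitions": dataclasses.asdict(ps.transitions),
        "disutility_components": list(ps.disutility_components.components),
        "service_utilisation": dict(ps.service_utilisation),
        "discount_rate": ps.discount_rate,
        "threshold_gbp_per_qaly": ps.threshold_gbp_per_qaly,
        "age_range": [ps.age_min, ps.age_max],
    }
    return json.dumps(payload, indent=2, default=enc)
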