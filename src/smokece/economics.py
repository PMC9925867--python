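"""Population aggregation and incremental cost-effectiveness analysis.

Lifetime discounted costs and QALYs from the per-starting-age cohort runs
are averaged over the age/sex population weights to give one expected
lifetime outcome per arm; pairwise comparison then yields incremental
cost (ΔC), incremental QALYs (ΔQ), the ICER = ΔC/ΔQ or a dominance
label, and the net monetary benefit NMB = λ·ΔQ − ΔC at a
willingness-to-pay threshold λ. An intervention is flagged cost-effective
iff NMB > 0 — equivalent to being dominant or having an ICER below λ in
the north-east quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ArmOutcome",
    "CEResult",
    "aggregate_population",
    "quitters_per_1000",
    "incremental_analysis",
]


@dataclass(frozen=True)
class ArmOutcome:
    """Population-average lifetime discounted outcomes for one arm."""

    arm_name: str
    cost_intervention: float
    cost_comorbidity: float
    qalys: float
    quit_prob_12m: float

    @property
    def cost_total(self) -> float:
        return self.cost_intervention + self.cost_comorbidity

    @property
    def quitters_per_1000(self) -> float:
        return 1000.0 * self.quit_prob_12m

    def validate(self) -> "ArmOutcome":
        if self.cost_intervention < 0 or self.cost_comorbidity < 0:
            raise ValueError(f"{self.arm_name}: negative cost")
        if self.qalys < 0:
            raise ValueError(f"{self.arm_name}: negative QALYs")
        if not 0.0 <= self.quit_prob_12m <= 1.0:
            raise ValueError(f"{self.arm_name}: quit probability outside [0, 1]")
        return self


def aggregate_population(cell_totals: Mapping[Tuple[int, str], Tuple[float, float, float]],
                         weights, *, arm_name: str = "",
                         quit_prob_12m: float = 0.0) -> ArmOutcome:
    """Weight per-(age, sex) lifetime totals into one population average.

    ``cell_totals`` maps (starting age, sex) to (intervention cost,
    comorbidity cost, QALYs), all discounted. Weights are normalised
    internally (rescaling them has no effect); every cell with positive
    weight must be present, and a missing one is reported by name.
    """
    total_w = 0.0
    acc = np.zeros(3)
    for i, age in enumerate(range(12, 101)):
        for j, sex in enumerate(("female", "male")):
            w = float(weights.w[i, j]) if hasattr(weights, "w") else float(weights[i, j])
            if w == 0.0:
                continue
            if w < 0:
                raise ValueError(f"negative weight at (age={age}, sex={sex})")
            if (age, sex) not in cell_totals:
                raise KeyError(f"missing cohort trace for (age={age}, sex={sex})")
            acc += w * np.asarray(cell_totals[(age, sex)], dtype=float)
            total_w += w
    if total_w <= 0:
        raise ValueError("population weights sum to zero")
    ci, cc, q = acc / total_w
    return ArmOutcome(arm_name, ci, cc, q, quit_prob_12m).validate()


def quitters_per_1000(quit_prob_intervention: float,
                      quit_prob_comparator: float) -> float:
    """Additional quitters per 1000 at 12 months (unrounded).

    Reporting rounds to the nearest integer; the unrounded difference is
    returned so downstream arithmetic never compounds rounding.
    """
    for p in (quit_prob_intervention, quit_prob_comparator):
        if not 0.0 <= p <= 1.0:
            raise ValueError("quit probabilities must lie in [0, 1]")
    return (quit_prob_intervention - quit_prob_comparator) * 1000.0


@dataclass(frozen=True)
class CEResult:
    """Pairwise incremental cost-effectiveness comparison.

    ``classification`` is one of ``"icer"`` (a ratio is meaningful),
    ``"dominant"`` (cheaper, no worse), ``"dominated"`` (costlier, no
    better) or ``"equivalent"`` (ΔC = ΔQ = 0). In the south-west quadrant
    (both increments negative) the ratio is reported with ``quadrant =
    "south_west"`` since a bare number is sign-ambiguous there.
    """

    intervention: ArmOutcome
    comparator: ArmOutcome
    threshold: float
    delta_cost_intervention: float
    delta_cost_comorbidity: float
    delta_cost: float
    delta_qalys: float
    classification: str
    icer: float | None
    quadrant: str | None
    nmb: float

    @property
    def cost_effective(self) -> bool:
        return self.nmb > 0.0

    @property
    def icer_label(self) -> str:
        if self.classification in ("dominant", "dominated", "equivalent"):
            return self.classification.capitalize()
        tag = " (SW)" if self.quadrant == "south_west" else ""
        return f"£{self.icer:,.0f}{tag}"

    def to_frame(self) -> pd.DataFrame:
        """Published-table layout: cost split, QALYs, ICER per row."""
        rows = []
        for a in (self.intervention, self.comparator):
            rows.append({
                "row": a.arm_name, "cost_intervention": round(a.cost_intervention),
                "cost_comorbidity": round(a.cost_comorbidity),
                "cost_total": round(a.cost_total),
                "qalys": round(a.qalys, 2), "icer": "-",
            })
        rows.append({
            "row": "incremental",
            "cost_intervention": round(self.delta_cost_intervention),
            "cost_comorbidity": round(self.delta_cost_comorbidity),
            "cost_total": round(self.delta_cost),
            "qalys": round(self.delta_qalys, 2),
            "icer": self.icer_label,
        })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"{self.intervention.arm_name} vs {self.comparator.arm_name}",
            self.to_frame().to_string(index=False),
            f"NMB at £{self.threshold:,.0f}/QALY: £{self.nmb:,.0f}"
            f"  (cost-effective: {self.cost_effective})",
        ]
        return "\n".join(lines)


def incremental_analysis(intervention: ArmOutcome, comparator: ArmOutcome,
                         threshold: float) -> CEResult:
    """Classify the comparison and compute ICER / dominance / NMB.

    All arithmetic is on unrounded values; rounding happens only in the
    reporting layer.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d_ci = intervention.cost_intervention - comparator.cost_intervention
    d_cc = intervention.cost_comorbidity - comparator.cost_comorbidity
    d_c = intervention.cost_total - comparator.cost_total
    d_q = intervention.qalys - comparator.qalys
    icer = None
    quadrant = None
    if d_c == 0.0 and d_q == 0.0:
        classification = "equivalent"
    elif d_c < 0.0 and d_q >= 0.0:
        classification = "dominant"
    elif d_c >= 0.0 and d_q <= 0.0:
        classification = "dominated"
    else:
        classification = "icer"
        icer = d_c / d_q
        quadrant = "north_east" if d_q > 0 else "south_west"
    nmb = threshold * d_q - d_c
    return CEResult(
        intervention=intervention, comparator=comparator, threshold=threshold,
        delta_cost_intervention=d_ci, delta_cost_comorbidity=d_cc,
        delta_cost=d_c, delta_qalys=d_q, classification=classification,
        icer=icer, quadrant=quadrant, nmb=nmb,
    )
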