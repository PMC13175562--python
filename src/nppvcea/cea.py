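"""Incremental cost-effectiveness comparison of two strategies.

Implements the standard cost-effectiveness plane logic: the incremental
cost-effectiveness ratio ICER = ΔC/ΔE where the ratio is meaningful,
dominance labels where it is not, and net monetary benefit
NMB = WTP·QALYs − cost. A strategy is cost-effective at a
willingness-to-pay threshold exactly when its incremental NMB is positive;
with a positive QALY gain this is the same as ICER strictly below WTP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

__all__ = ["ArmTotals", "CEAResult", "compare"]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED_ICER = "undefined-ICER"


@dataclass(frozen=True)
class ArmTotals:
    """Discounted lifetime totals for one strategy."""

    arm: str
    cost: float
    qalys: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: ArmTotals
    comparator: ArmTotals
    wtp: float
    delta_cost: float
    delta_effect: float
    icer: float | None  # None when a dominance/undefined label applies
    label: str | None  # 'dominant', 'dominated', 'undefined-ICER' or None
    nmb_intervention: float
    nmb_comparator: float
    cost_effective: bool

    @property
    def incremental_nmb(self) -> float:
        return self.nmb_intervention - self.nmb_comparator

    def to_record(self) -> dict:
        return {
            "intervention_arm": self.intervention.arm,
            "comparator_arm": self.comparator.arm,
            "intervention_cost": self.intervention.cost,
            "comparator_cost": self.comparator.cost,
            "intervention_qalys": self.intervention.qalys,
            "comparator_qalys": self.comparator.qalys,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "label": self.label,
            "wtp": self.wtp,
            "nmb_intervention": self.nmb_intervention,
            "nmb_comparator": self.nmb_comparator,
            "incremental_nmb": self.incremental_nmb,
            "cost_effective": self.cost_effective,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_record()])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_record(), fh, indent=1)
            fh.write("\n")


def compare(
    intervention: ArmTotals, comparator: ArmTotals, wtp: float
) -> CEAResult:
    """Compare two strategies' totals at a willingness-to-pay threshold.

    Quadrant logic: cheaper-and-more-effective is 'dominant' (no ratio),
    costlier-and-less-effective is 'dominated'; a zero QALY difference gives
    an 'undefined-ICER' label with cost-effectiveness decided by the sign of
    the cost difference. Otherwise the ICER is reported and compared
    strictly against WTP (equality is not cost-effective). In every quadrant
    the verdict coincides with incremental NMB > 0.
    """
    d_cost = intervention.cost - comparator.cost
    d_eff = intervention.qalys - comparator.qalys
    nmb_i = wtp * intervention.qalys - intervention.cost
    nmb_c = wtp * comparator.qalys - comparator.cost

    icer: float | None = None
    label: str | None = None
    if d_eff > 0 and d_cost < 0:
        label = DOMINANT
        cost_effective = True
    elif d_eff < 0 and d_cost > 0:
        label = DOMINATED
        cost_effective = False
    elif d_eff == 0:
        label = UNDEFINED_ICER
        cost_effective = d_cost < 0
    else:
        icer = d_cost / d_eff
        # ICER strictly below WTP (gaining QALYs) or strictly above (losing
        # QALYs at savings beyond WTP) — identical to a positive NMB gain
        cost_effective = nmb_i - nmb_c > 0

    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        label=label,
        nmb_intervention=nmb_i,
        nmb_comparator=nmb_c,
        cost_effective=cost_effective,
    )
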