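"""Expected-cost probability tree and national burden scaling.

The model is a two-branch probability tree per glycemic group:

* mother: one chance node over the six delivery DRGs (370-375), each leaf
  carrying its LOS-adjusted tariff;
* infant: a macrosomia chance node followed by a conditional outcome node
  (hypoglycemia, hyperbilirubinemia, shoulder dystocia, respiratory
  distress, brachial plexus injury, or normal newborn), each outcome
  carrying one group-independent cost.

Expected inpatient cost per case is the probability-weighted sum over
leaves; total cost per case adds the outpatient component.  The national
burden multiplies the GDM case count (births x prevalence) by the
GDM - euglycemia difference in total cost per case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .outpatient import gdm_outpatient_cost, group_outpatient_cost
from .parameters import (
    DELIVERY_CATEGORIES,
    GROUPS,
    INFANT_OUTCOMES,
    MACRO_STRATA,
    DeliveryMix,
    InfantOutcomeModel,
    ModelParameters,
    validate,
)


@dataclass(frozen=True)
class GroupCosts:
    """Cost-per-case components for one group (or for the GDM-euglycemia delta)."""

    outpatient: float
    mother_inpatient: float
    infant_inpatient: float

    @property
    def inpatient_total(self) -> float:
        return self.mother_inpatient + self.infant_inpatient

    @property
    def total(self) -> float:
        return self.outpatient + self.inpatient_total


@dataclass(frozen=True)
class CostBreakdown:
    euglycemia: GroupCosts
    gdm: GroupCosts

    @property
    def delta(self) -> GroupCosts:
        return GroupCosts(
            outpatient=self.gdm.outpatient - self.euglycemia.outpatient,
            mother_inpatient=self.gdm.mother_inpatient - self.euglycemia.mother_inpatient,
            infant_inpatient=self.gdm.infant_inpatient - self.euglycemia.infant_inpatient,
        )

    def group(self, name: str) -> GroupCosts:
        return {"euglycemia": self.euglycemia, "gdm": self.gdm}[name]


@dataclass(frozen=True)
class BurdenEstimate:
    gdm_cases: int
    incremental_cost: float
    relative_increase: float


@dataclass(frozen=True)
class TreeLeaf:
    """One terminal node: its branch path, joint probability and cost."""

    path: tuple[str, ...]
    probability: float
    cost: float


def mother_inpatient_cost(mix: DeliveryMix, group: str) -> float:
    """Expected delivery-stay cost: sum of probability x cost over the DRGs."""
    return sum(
        mix.probability(group, d) * mix.cost(group, d) for d in DELIVERY_CATEGORIES
    )


def infant_inpatient_cost(model: InfantOutcomeModel, group: str) -> float:
    """Expected neonatal cost over the macrosomia-stratified outcome node."""
    p_macro = model.macrosomia_prob[group]
    expected = 0.0
    for stratum, weight in (("macrosomia", p_macro), ("no_macrosomia", 1.0 - p_macro)):
        vec = model.conditional_probs[group][stratum]
        expected += weight * sum(
            vec[o] * model.outcome_costs[o] for o in INFANT_OUTCOMES
        )
    return expected


def cost_per_case(params: ModelParameters) -> CostBreakdown:
    """Assemble outpatient, mother and infant expected costs for both groups."""
    violations = validate(params)
    if violations:
        from .parameters import ValidationError

        raise ValidationError(violations)
    groups = {}
    for g in GROUPS:
        if g == "gdm":
            outpatient = gdm_outpatient_cost(params)
        else:
            outpatient = group_outpatient_cost(params, g).total
        groups[g] = GroupCosts(
            outpatient=outpatient,
            mother_inpatient=mother_inpatient_cost(params.delivery_mix, g),
            infant_inpatient=infant_inpatient_cost(params.infant_model, g),
        )
    return CostBreakdown(euglycemia=groups["euglycemia"], gdm=groups["gdm"])


def national_burden(params: ModelParameters, breakdown: CostBreakdown) -> BurdenEstimate:
    """Scale the per-case difference to the national annual case count."""
    # round half-up: 502,596 x 0.109 = 54,782.96 -> 54,783
    cases = int(math.floor(params.births * params.gdm_prevalence + 0.5))
    delta = breakdown.delta.total
    return BurdenEstimate(
        gdm_cases=cases,
        incremental_cost=cases * delta,
        relative_increase=delta / breakdown.euglycemia.total,
    )


def enumerate_tree(params: ModelParameters, group: str) -> list[TreeLeaf]:
    """Exhaustive leaf listing; the brute-force counterpart of the closed forms.

    Returns the 6 delivery leaves and the 12 (macrosomia status x outcome)
    infant leaves.  Within each branch system the leaf probabilities sum to
    1, and the probability-weighted cost over all leaves equals
    mother_inpatient_cost + infant_inpatient_cost.
    """
    leaves = []
    mix = params.delivery_mix
    for d in DELIVERY_CATEGORIES:
        leaves.append(
            TreeLeaf(
                path=(group, "delivery", d),
                probability=mix.probability(group, d),
                cost=mix.cost(group, d),
            )
        )
    infant = params.infant_model
    p_macro = infant.macrosomia_prob[group]
    stratum_prob = {"macrosomia": p_macro, "no_macrosomia": 1.0 - p_macro}
    for stratum in MACRO_STRATA:
        vec = infant.conditional_probs[group][stratum]
        for outcome in INFANT_OUTCOMES:
            leaves.append(
                TreeLeaf(
                    path=(group, "infant", stratum, outcome),
                    probability=stratum_prob[stratum] * vec[outcome],
                    cost=infant.outcome_costs[outcome],
                )
            )
    return leaves
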