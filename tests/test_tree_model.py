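import dataclasses

import pytest
from hypothesis import given

from gdmburden.parameters import (
    DELIVERY_CATEGORIES,
    GROUPS,
    DeliveryMix,
    default_parameters,
)
from gdmburden.tree_model import (
    cost_per_case,
    enumerate_tree,
    infant_inpatient_cost,
    mother_inpatient_cost,
    national_burden,
)
from .conftest import valid_model_parameters


def test_degenerate_mix_returns_that_category_cost(params):
    probs = {g: {d: 0.0 for d in DELIVERY_CATEGORIES} for g in GROUPS}
    for g in GROUPS:
        probs[g]["371"] = 1.0
    mix = DeliveryMix(costs=params.delivery_mix.costs, probs=probs)
    assert mother_inpatient_cost(mix, "gdm") == pytest.approx(2373.0)


def test_certain_normal_newborn_costs_the_normal_tariff(params):
    infant = params.infant_model
    certain = {
        g: {
            s: {o: (1.0 if o == "normal_newborn" else 0.0) for o in v}
            for s, v in infant.conditional_probs[g].items()
        }
        for g in GROUPS
    }
    model = dataclasses.replace(infant, conditional_probs=certain)
    assert infant_inpatient_cost(model, "euglycemia") == pytest.approx(560.0)


def test_breakdown_internal_consistency(params):
    bd = cost_per_case(params)
    for g in GROUPS:
        gc = bd.group(g)
        assert gc.total == pytest.approx(
            gc.outpatient + gc.mother_inpatient + gc.infant_inpatient, abs=1e-9
        )
    assert bd.delta.total == pytest.approx(bd.gdm.total - bd.euglycemia.total, abs=1e-9)


def test_zero_prevalence_means_zero_burden(params):
    p = dataclasses.replace(params, gdm_prevalence=0.0)
    burden = national_burden(p, cost_per_case(p))
    assert burden.gdm_cases == 0
    assert burden.incremental_cost == 0.0


def test_equal_groups_leave_only_the_screening_difference(params):
    """With identical inpatient parameters and no insulin treatment, the
    whole GDM excess is the diet-group screening/monitoring cost."""
    mix = params.delivery_mix
    eq_mix = DeliveryMix(
        costs={g: dict(mix.costs["euglycemia"]) for g in GROUPS},
        counts={g: dict(mix.counts["euglycemia"]) for g in GROUPS},
    )
    infant = params.infant_model
    eq_infant = dataclasses.replace(
        infant,
        macrosomia_prob={g: infant.macrosomia_prob["euglycemia"] for g in GROUPS},
        conditional_probs={
            g: {s: dict(v) for s, v in infant.conditional_probs["euglycemia"].items()}
            for g in GROUPS
        },
    )
    p = dataclasses.replace(
        params, delivery_mix=eq_mix, infant_model=eq_infant, insulin_share=0.0
    )
    bd = cost_per_case(p)
    assert bd.delta.mother_inpatient == pytest.approx(0.0, abs=1e-9)
    assert bd.delta.infant_inpatient == pytest.approx(0.0, abs=1e-9)
    from gdmburden.outpatient import group_outpatient_cost

    screening_diff = (
        group_outpatient_cost(p, "gdm_diet").total
        - group_outpatient_cost(p, "euglycemia").total
    )
    assert bd.delta.total == pytest.approx(screening_diff, abs=1e-9)


def test_doubling_all_costs_doubles_all_totals(params):
    mix = params.delivery_mix
    doubled_mix = DeliveryMix(
        costs={g: {d: 2 * c for d, c in mix.costs[g].items()} for g in GROUPS},
        counts=mix.counts,
    )
    infant = dataclasses.replace(
        params.infant_model,
        outcome_costs={o: 2 * c for o, c in params.infant_model.outcome_costs.items()},
    )
    items = tuple(
        dataclasses.replace(it, unit_cost=2 * it.unit_cost)
        for it in params.resource_items
    )
    doubled = dataclasses.replace(
        params, delivery_mix=doubled_mix, infant_model=infant, resource_items=items
    )
    base, scaled = cost_per_case(params), cost_per_case(doubled)
    for g in GROUPS:
        assert scaled.group(g).total == pytest.approx(2 * base.group(g).total)


@given(random_params=valid_model_parameters())
def test_tree_enumeration_matches_closed_form(random_params):
    """The exhaustive leaf expectation is the oracle for the closed-form
    expected-cost sums, on arbitrary valid parameter sets."""
    for g in GROUPS:
        leaves = enumerate_tree(random_params, g)
        delivery = [l for l in leaves if l.path[1] == "delivery"]
        infant = [l for l in leaves if l.path[1] == "infant"]
        assert len(delivery) == 6 and len(infant) == 12
        assert sum(l.probability for l in delivery) == pytest.approx(1.0, abs=1e-9)
        assert sum(l.probability for l in infant) == pytest.approx(1.0, abs=1e-9)

        expected = sum(l.probability * l.cost for l in leaves)
        closed = mother_inpatient_cost(
            random_params.delivery_mix, g
        ) + infant_inpatient_cost(random_params.infant_model, g)
        assert expected == pytest.approx(closed, rel=1e-12)

        # each branch expectation lies within its leaf-cost envelope
        for system in (delivery, infant):
            ev = sum(l.probability * l.cost for l in system)
            assert min(l.cost for l in system) - 1e-9 <= ev
            assert ev <= max(l.cost for l in system) + 1e-9


def test_specific_leaf_probability(params):
    leaves = enumerate_tree(params, "euglycemia")
    (leaf,) = [
        l
        for l in leaves
        if l.path[1:] == ("infant", "macrosomia", "respiratory_distress")
    ]
    assert leaf.probability == pytest.approx(0.074 * 0.017)
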