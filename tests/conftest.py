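import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from gdmburden.parameters import (
    DELIVERY_CATEGORIES,
    GROUPS,
    INFANT_OUTCOMES,
    MACRO_STRATA,
    DeliveryMix,
    InfantOutcomeModel,
    default_parameters,
)
from dataclasses import replace

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


def _normalized(values):
    total = sum(values)
    return [v / total for v in values]


@st.composite
def valid_model_parameters(draw):
    """Random structurally valid parameter sets (probabilities normalised,
    costs positive) for property tests of the tree algebra."""
    base = default_parameters()
    pos = st.floats(0.01, 1.0, allow_nan=False)
    money = st.floats(100.0, 30000.0, allow_nan=False)

    probs, costs = {}, {}
    for g in GROUPS:
        raw = draw(st.lists(pos, min_size=6, max_size=6))
        probs[g] = dict(zip(DELIVERY_CATEGORIES, _normalized(raw)))
        costs[g] = {
            d: draw(money) for d in DELIVERY_CATEGORIES
        }
    mix = DeliveryMix(costs=costs, probs=probs)

    macro = {g: draw(st.floats(0.0, 1.0)) for g in GROUPS}
    cond = {}
    for g in GROUPS:
        cond[g] = {}
        for s in MACRO_STRATA:
            raw = draw(st.lists(pos, min_size=6, max_size=6))
            cond[g][s] = dict(zip(INFANT_OUTCOMES, _normalized(raw)))
    infant = InfantOutcomeModel(
        macrosomia_prob=macro,
        conditional_probs=cond,
        outcome_costs={o: draw(money) for o in INFANT_OUTCOMES},
    )
    return replace(base, delivery_mix=mix, infant_model=infant)
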