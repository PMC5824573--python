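"""Antenatal outpatient costing over the third-trimester horizon.

Cost per case for each glycemic group is the sum over resource items of
unit cost times the number of units consumed in the 90-day horizon.  For
items prescribed "every x–y weeks" the conservative lower-bound rule
applies: the widest interval (y weeks) gives the fewest events, so the
count is floor((horizon/7) / y).  The GDM group's figure is the
insulin-share-weighted mean of the diet- and insulin-treated costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import (
    OUTPATIENT_GROUPS,
    FrequencySpec,
    ModelParameters,
)


@dataclass(frozen=True)
class OutpatientCost:
    """Per-item and total outpatient cost for one treatment group."""

    group: str
    per_item: dict[str, float]
    total: float


def consumption_count(freq: FrequencySpec, horizon_days: int) -> float:
    """Number of units consumed over the horizon under the lower-bound rule."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    if freq.kind == "none":
        return 0.0
    if freq.kind == "per_day":
        return freq.value * horizon_days
    if freq.kind == "per_horizon":
        return float(freq.value)
    if freq.kind == "interval_weeks":
        # widest interval -> fewest events (conservative)
        return float(math.floor((horizon_days / 7.0) / freq.high_weeks))
    raise ValueError(f"unknown frequency kind {freq.kind!r}")


def group_outpatient_cost(params: ModelParameters, group: str) -> OutpatientCost:
    """Outpatient cost breakdown for one of the three treatment groups."""
    if group not in OUTPATIENT_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {OUTPATIENT_GROUPS}")
    per_item = {}
    for item in params.resource_items:
        count = consumption_count(item.frequency(group), params.horizon_days)
        per_item[item.name] = item.unit_cost * count
    return OutpatientCost(group=group, per_item=per_item, total=sum(per_item.values()))


def weighted_gdm_outpatient(diet: float, insulin: float, insulin_share: float) -> float:
    """Insulin-share-weighted mean of diet- and insulin-treated costs."""
    if not 0.0 <= insulin_share <= 1.0:
        raise ValueError("insulin_share must lie in [0, 1]")
    return (1.0 - insulin_share) * diet + insulin_share * insulin


def gdm_outpatient_cost(params: ModelParameters) -> float:
    """Weighted GDM outpatient cost per case from the full parameter set."""
    diet = group_outpatient_cost(params, "gdm_diet").total
    insulin = group_outpatient_cost(params, "gdm_insulin").total
    return weighted_gdm_outpatient(diet, insulin, params.insulin_share)
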