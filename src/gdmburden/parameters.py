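"""Model parameters for the short-term economic burden of GDM in Italy.

Everything the model needs is held in one validated, immutable-by-convention
structure (:class:`ModelParameters`):

* antenatal outpatient resource items with per-group consumption frequencies
  over the 90-day third trimester,
* the delivery mix — probabilities (stored as exact admission-count ratios)
  and LOS-adjusted DRG tariff costs for the six delivery DRGs 370–375, by
  maternal glycemic status,
* the macrosomia-stratified neonatal outcome model (probabilities per group
  and per macrosomia status; one cost per outcome),
* population figures: annual births, GDM prevalence, insulin-treated share.

:func:`default_parameters` ships the Italian 2014 national base case.
Alternative parameter sets load from a YAML config that mirrors this
structure; unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

# Maternal glycemic groups. Outpatient costing distinguishes diet- and
# insulin-treated GDM; the delivery/neonatal tree only knows gdm vs euglycemia.
GROUPS = ("euglycemia", "gdm")
OUTPATIENT_GROUPS = ("euglycemia", "gdm_diet", "gdm_insulin")

# Delivery DRGs (Italian DRG system, codes 370-375).
DELIVERY_CATEGORIES = ("370", "371", "372", "373", "374", "375")
CATEGORY_LABELS: Mapping[str, str] = {
    "370": "caesarean_with_cc",
    "371": "caesarean_without_cc",
    "372": "vaginal_with_cc",
    "373": "vaginal_without_cc",
    "374": "vaginal_sterilization_dc",
    "375": "vaginal_other_interventions",
}
LABEL_TO_CATEGORY = {v: k for k, v in CATEGORY_LABELS.items()}

# Neonatal outcomes; mutually exclusive in the tree, normal_newborn closes
# each conditional vector to 1 ("obtained by difference").
INFANT_OUTCOMES = (
    "hypoglycemia",
    "hyperbilirubinemia",
    "shoulder_dystocia",
    "respiratory_distress",
    "brachial_plexus_injury",
    "normal_newborn",
)
MACRO_STRATA = ("macrosomia", "no_macrosomia")

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class FrequencySpec:
    """How often a resource item is consumed by one group.

    kind:
        ``per_day``        — ``value`` units every day of the horizon
        ``per_horizon``    — ``value`` units in total over the horizon
        ``interval_weeks`` — one event every ``low_weeks``–``high_weeks``
                             weeks (the costing rule takes the conservative
                             lower bound, i.e. the widest interval)
        ``none``           — not consumed
    """

    kind: str
    value: float | None = None
    low_weeks: int | None = None
    high_weeks: int | None = None

    KINDS = ("per_day", "per_horizon", "interval_weeks", "none")

    @classmethod
    def per_day(cls, value: float) -> "FrequencySpec":
        return cls("per_day", value=value)

    @classmethod
    def per_horizon(cls, value: float) -> "FrequencySpec":
        return cls("per_horizon", value=value)

    @classmethod
    def every_weeks(cls, low: int, high: int) -> "FrequencySpec":
        return cls("interval_weeks", low_weeks=low, high_weeks=high)

    @classmethod
    def none(cls) -> "FrequencySpec":
        return cls("none")

    def violations(self, where: str) -> list[str]:
        out = []
        if self.kind not in self.KINDS:
            out.append(f"{where}: unknown frequency kind {self.kind!r}")
            return out
        if self.kind == "per_day" and not (self.value is not None and self.value > 0):
            out.append(f"{where}: per_day frequency requires value > 0")
        if self.kind == "per_horizon" and not (
            self.value is not None and self.value >= 0
        ):
            out.append(f"{where}: per_horizon frequency requires value >= 0")
        if self.kind == "interval_weeks":
            if self.low_weeks is None or self.high_weeks is None:
                out.append(f"{where}: interval_weeks requires low_weeks and high_weeks")
            elif not (0 < self.low_weeks <= self.high_weeks):
                out.append(
                    f"{where}: interval_weeks requires 0 < low_weeks <= high_weeks"
                )
        return out


@dataclass(frozen=True)
class ResourceItem:
    """One antenatal outpatient resource with per-group consumption.

    Groups absent from ``group_consumption`` do not consume the item.
    A free item (e.g. the loaned glucometer) has ``unit_cost`` 0.
    """

    name: str
    unit_cost: float
    group_consumption: Mapping[str, FrequencySpec]

    def frequency(self, group: str) -> FrequencySpec:
        return self.group_consumption.get(group, FrequencySpec.none())

    def violations(self) -> list[str]:
        out = []
        if self.unit_cost < 0:
            out.append(f"resource_items[{self.name}]: unit_cost must be >= 0")
        for g, freq in self.group_consumption.items():
            if g not in OUTPATIENT_GROUPS:
                out.append(f"resource_items[{self.name}]: unknown group {g!r}")
            out.extend(freq.violations(f"resource_items[{self.name}].{g}"))
        return out


@dataclass(frozen=True)
class DeliveryMix:
    """Per-group delivery probabilities and per-stay costs for DRGs 370-375.

    Where admission counts are known they are stored (``counts``) and the
    probabilities are the exact count ratios; ``probs`` is only stored
    directly when no counts exist (e.g. a mix estimated from records).
    """

    costs: Mapping[str, Mapping[str, float]]  # group -> drg -> money
    counts: Mapping[str, Mapping[str, int]] | None = None
    probs: Mapping[str, Mapping[str, float]] | None = None

    def group_total(self, group: str) -> int:
        assert self.counts is not None
        return sum(self.counts[group].values())

    def probability(self, group: str, drg: str) -> float:
        if self.counts is not None:
            return self.counts[group][drg] / self.group_total(group)
        assert self.probs is not None
        return self.probs[group][drg]

    def probability_vector(self, group: str) -> dict[str, float]:
        return {d: self.probability(group, d) for d in DELIVERY_CATEGORIES}

    def cost(self, group: str, drg: str) -> float:
        return self.costs[group][drg]

    def violations(self) -> list[str]:
        out = []
        if self.counts is None and self.probs is None:
            return ["delivery_mix: needs either counts or probs"]
        for g in GROUPS:
            source = self.counts if self.counts is not None else self.probs
            if g not in source:
                out.append(f"delivery_mix: missing group {g!r}")
                continue
            missing = [d for d in DELIVERY_CATEGORIES if d not in source[g]]
            if missing:
                out.append(f"delivery_mix[{g}]: missing categories {missing}")
                continue
            total = sum(self.probability(g, d) for d in DELIVERY_CATEGORIES)
            if abs(total - 1.0) > 1e-9:
                out.append(
                    f"delivery_mix[{g}]: probabilities sum to {total:.6f}, not 1"
                )
            for d in DELIVERY_CATEGORIES:
                if not self.probability(g, d) >= 0:
                    out.append(f"delivery_mix[{g}][{d}]: negative probability")
                if g not in self.costs or d not in self.costs[g]:
                    out.append(f"delivery_mix.costs[{g}][{d}]: missing")
                elif not self.costs[g][d] > 0:
                    out.append(f"delivery_mix.costs[{g}][{d}]: cost must be > 0")
        return out


@dataclass(frozen=True)
class InfantOutcomeModel:
    """Macrosomia-stratified neonatal outcome probabilities and costs.

    ``conditional_probs[group][stratum][outcome]`` must sum to 1 over the
    outcomes within each (group, stratum); ``normal_newborn`` is the closing
    complement.  Outcome costs are group-independent: the discharge database
    cannot attribute an infant to a GDM or euglycemic mother.
    """

    macrosomia_prob: Mapping[str, float]  # group -> p
    conditional_probs: Mapping[str, Mapping[str, Mapping[str, float]]]
    outcome_costs: Mapping[str, float]  # outcome -> money

    def violations(self) -> list[str]:
        out = []
        for g in GROUPS:
            p = self.macrosomia_prob.get(g)
            if p is None:
                out.append(f"infant_model.macrosomia_prob[{g}]: missing")
            elif not (0.0 <= p <= 1.0):
                out.append(f"infant_model.macrosomia_prob[{g}]: {p} outside [0, 1]")
            for stratum in MACRO_STRATA:
                try:
                    vec = self.conditional_probs[g][stratum]
                except KeyError:
                    out.append(f"infant_model.conditional_probs[{g}][{stratum}]: missing")
                    continue
                missing = [o for o in INFANT_OUTCOMES if o not in vec]
                if missing:
                    out.append(
                        f"infant_model.conditional_probs[{g}][{stratum}]: "
                        f"missing outcomes {missing}"
                    )
                    continue
                for o in INFANT_OUTCOMES:
                    if not (0.0 <= vec[o] <= 1.0):
                        out.append(
                            f"infant_model.conditional_probs[{g}][{stratum}][{o}]: "
                            f"{vec[o]} outside [0, 1]"
                        )
                total = sum(vec[o] for o in INFANT_OUTCOMES)
                if abs(total - 1.0) > _PROB_TOL:
                    out.append(
                        f"infant_model.conditional_probs[{g}][{stratum}]: "
                        f"sum {total:.6f}, not 1"
                    )
        for o in INFANT_OUTCOMES:
            c = self.outcome_costs.get(o)
            if c is None:
                out.append(f"infant_model.outcome_costs[{o}]: missing")
            elif not c > 0:
                out.append(f"infant_model.outcome_costs[{o}]: cost must be > 0")
        return out


@dataclass(frozen=True)
class ModelParameters:
    """The complete parameter set of the burden model."""

    resource_items: tuple[ResourceItem, ...]
    delivery_mix: DeliveryMix
    infant_model: InfantOutcomeModel
    insulin_share: float  # share of GDM women treated with insulin
    horizon_days: int  # modelled trimester length, days
    births: int  # annual national births (proxy for pregnancies)
    gdm_prevalence: float

    def violations(self) -> list[str]:
        out = []
        for item in self.resource_items:
            out.extend(item.violations())
        out.extend(self.delivery_mix.violations())
        out.extend(self.infant_model.violations())
        if not (0.0 <= self.insulin_share <= 1.0):
            out.append(f"insulin_share: {self.insulin_share} outside [0, 1]")
        if not self.horizon_days > 0:
            out.append("horizon_days: must be > 0")
        if not self.births > 0:
            out.append("births: must be > 0")
        if not (0.0 <= self.gdm_prevalence <= 1.0):
            out.append(f"gdm_prevalence: {self.gdm_prevalence} outside [0, 1]")
        return out


def validate(params: ModelParameters) -> list[str]:
    """Return a list of human-readable invariant violations (empty == valid)."""
    return params.violations()


# --------------------------------------------------------------------------
# Default (Italian 2014 national) parameter set
# --------------------------------------------------------------------------

_F = FrequencySpec

_DEFAULT_RESOURCE_ITEMS: tuple[ResourceItem, ...] = (
    # Screening / post-partum check: GDM women repeat the 75 g OGTT shortly
    # after delivery, hence 2 tests vs 1 in euglycemia.
    ResourceItem(
        "ogtt_75g",
        2.38,
        {
            "gdm_diet": _F.per_horizon(2),
            "gdm_insulin": _F.per_horizon(2),
            "euglycemia": _F.per_horizon(1),
        },
    ),
    # Self-monitoring kit: glucometer is loaned free of charge.
    ResourceItem(
        "glucometer",
        0.0,
        {"gdm_diet": _F.per_horizon(1), "gdm_insulin": _F.per_horizon(1)},
    ),
    ResourceItem(
        "test_strip",
        0.55,
        {"gdm_diet": _F.per_day(2), "gdm_insulin": _F.per_day(4)},
    ),
    ResourceItem(
        "finger_stick",
        0.10,
        {"gdm_diet": _F.per_day(2), "gdm_insulin": _F.per_day(4)},
    ),
    # Insulin therapy: 1-2 shots/day prescribed; the conservative lower
    # bound (1/day) is what the consumption rule applies.
    ResourceItem("insulin_shot", 6.34, {"gdm_insulin": _F.per_day(1)}),
    ResourceItem("needle", 0.14, {"gdm_insulin": _F.per_day(1)}),
    ResourceItem("syringe", 0.11, {"gdm_insulin": _F.per_day(1)}),
    ResourceItem(
        "obstetric_visit",
        20.66,
        {
            "gdm_diet": _F.every_weeks(3, 4),
            "gdm_insulin": _F.every_weeks(1, 2),
            "euglycemia": _F.every_weeks(5, 6),
        },
    ),
    # Two extra scans at weeks 32 and 36 in GDM.
    ResourceItem(
        "obstetric_ultrasound",
        30.99,
        {"gdm_diet": _F.per_horizon(2), "gdm_insulin": _F.per_horizon(2)},
    ),
    ResourceItem(
        "visual_field_test",
        16.78,
        {"gdm_diet": _F.per_horizon(1), "gdm_insulin": _F.per_horizon(1)},
    ),
)

# Delivery admission counts by DRG and glycemic status, Italian HDD 2014.
_DEFAULT_DELIVERY_COUNTS = {
    "euglycemia": {
        "370": 11437,
        "371": 145212,
        "372": 9447,
        "373": 260036,
        "374": 4274,
        "375": 445,
    },
    "gdm": {"370": 538, "371": 4019, "372": 447, "373": 6287, "374": 125, "375": 18},
}

# LOS-adjusted DRG tariffs (EUR per delivery stay).
_DEFAULT_DELIVERY_COSTS = {
    "euglycemia": {
        "370": 2774.5,
        "371": 2084.3,
        "372": 1610.3,
        "373": 1269.3,
        "374": 2116.0,
        "375": 2842.0,
    },
    "gdm": {
        "370": 2938.5,
        "371": 2373.0,
        "372": 1802.8,
        "373": 1385.2,
        "374": 2330.9,
        "375": 3265.9,
    },
}

_DEFAULT_MACROSOMIA = {"euglycemia": 0.074, "gdm": 0.087}

_DEFAULT_CONDITIONAL = {
    "euglycemia": {
        "macrosomia": {
            "hypoglycemia": 0.024,
            "hyperbilirubinemia": 0.076,
            "shoulder_dystocia": 0.060,
            "respiratory_distress": 0.017,
            "brachial_plexus_injury": 0.007,
            "normal_newborn": 0.816,
        },
        "no_macrosomia": {
            "hypoglycemia": 0.012,
            "hyperbilirubinemia": 0.091,
            "shoulder_dystocia": 0.009,
            "respiratory_distress": 0.012,
            "brachial_plexus_injury": 0.001,
            "normal_newborn": 0.875,
        },
    },
    "gdm": {
        "macrosomia": {
            "hypoglycemia": 0.053,
            "hyperbilirubinemia": 0.132,
            "shoulder_dystocia": 0.105,
            "respiratory_distress": 0.040,
            "brachial_plexus_injury": 0.026,
            "normal_newborn": 0.644,
        },
        "no_macrosomia": {
            "hypoglycemia": 0.026,
            "hyperbilirubinemia": 0.104,
            "shoulder_dystocia": 0.016,
            "respiratory_distress": 0.015,
            "brachial_plexus_injury": 0.002,
            "normal_newborn": 0.837,
        },
    },
}

# Mean reimbursement tariff per neonatal event (EUR); normal newborn is the
# DRG 391 tariff.
_DEFAULT_OUTCOME_COSTS = {
    "respiratory_distress": 24337.8,
    "hypoglycemia": 6571.8,
    "hyperbilirubinemia": 2854.2,
    "brachial_plexus_injury": 1671.9,
    "shoulder_dystocia": 1407.6,
    "normal_newborn": 560.0,
}


def default_parameters() -> ModelParameters:
    """The packaged Italian 2014 base case."""
    return ModelParameters(
        resource_items=_DEFAULT_RESOURCE_ITEMS,
        delivery_mix=DeliveryMix(
            costs=copy.deepcopy(_DEFAULT_DELIVERY_COSTS),
            counts=copy.deepcopy(_DEFAULT_DELIVERY_COUNTS),
        ),
        infant_model=InfantOutcomeModel(
            macrosomia_prob=dict(_DEFAULT_MACROSOMIA),
            conditional_probs=copy.deepcopy(_DEFAULT_CONDITIONAL),
            outcome_costs=dict(_DEFAULT_OUTCOME_COSTS),
        ),
        insulin_share=0.14,
        horizon_days=90,
        births=502_596,
        gdm_prevalence=0.109,
    )


# --------------------------------------------------------------------------
# Config file I/O
# --------------------------------------------------------------------------


class ConfigError(ValueError):
    """Raised for unparseable configs or unknown keys."""


class ValidationError(ValueError):
    """Raised when a loaded parameter set violates model invariants."""

    def __init__(self, violations: Iterable[str]):
        self.violations = list(violations)
        super().__init__("invalid parameters:\n  " + "\n  ".join(self.violations))


_TOP_SECTIONS = ("outpatient", "delivery", "infant", "population")
_POPULATION_KEYS = ("births", "gdm_prevalence", "insulin_share", "horizon_days")


def _freq_to_dict(freq: FrequencySpec) -> dict:
    if freq.kind == "interval_weeks":
        return {
            "kind": freq.kind,
            "low_weeks": freq.low_weeks,
            "high_weeks": freq.high_weeks,
        }
    if freq.kind == "none":
        return {"kind": "none"}
    return {"kind": freq.kind, "value": freq.value}


def _freq_from_dict(d: Mapping, where: str) -> FrequencySpec:
    extra = set(d) - {"kind", "value", "low_weeks", "high_weeks"}
    if extra:
        raise ConfigError(f"{where}: unknown keys {sorted(extra)}")
    if "kind" not in d:
        raise ConfigError(f"{where}: frequency needs a 'kind'")
    return FrequencySpec(
        kind=d["kind"],
        value=d.get("value"),
        low_weeks=d.get("low_weeks"),
        high_weeks=d.get("high_weeks"),
    )


def parameters_to_dict(params: ModelParameters) -> dict:
    """Serialise a parameter set into the config-file structure."""
    delivery: dict = {"costs": {g: dict(params.delivery_mix.costs[g]) for g in GROUPS}}
    if params.delivery_mix.counts is not None:
        delivery["counts"] = {g: dict(params.delivery_mix.counts[g]) for g in GROUPS}
    else:
        delivery["probs"] = {g: dict(params.delivery_mix.probs[g]) for g in GROUPS}
    return {
        "outpatient": {
            "items": [
                {
                    "name": it.name,
                    "unit_cost": it.unit_cost,
                    "consumption": {
                        g: _freq_to_dict(f) for g, f in it.group_consumption.items()
                    },
                }
                for it in params.resource_items
            ]
        },
        "delivery": delivery,
        "infant": {
            "macrosomia_prob": dict(params.infant_model.macrosomia_prob),
            "conditional_probs": {
                g: {s: dict(v) for s, v in params.infant_model.conditional_probs[g].items()}
                for g in GROUPS
            },
            "outcome_costs": dict(params.infant_model.outcome_costs),
        },
        "population": {
            "births": params.births,
            "gdm_prevalence": params.gdm_prevalence,
            "insulin_share": params.insulin_share,
            "horizon_days": params.horizon_days,
        },
    }


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Dump the active parameter set as YAML (round-trips with load)."""
    Path(path).write_text(
        yaml.safe_dump(parameters_to_dict(params), sort_keys=False)
    )


def _check_keys(d: Mapping, allowed: Iterable[str], where: str) -> None:
    extra = set(d) - set(allowed)
    if extra:
        raise ConfigError(f"{where}: unknown keys {sorted(extra)}")


def parameters_from_dict(config: Mapping) -> ModelParameters:
    """Build ModelParameters from a (possibly partial) config dict.

    Sections or fields absent from the config keep their default values.
    Unknown keys anywhere raise :class:`ConfigError`.
    """
    base = default_parameters()
    _check_keys(config, _TOP_SECTIONS, "config")

    resource_items = base.resource_items
    out_cfg = config.get("outpatient") or {}
    _check_keys(out_cfg, ("items",), "outpatient")
    if "items" in out_cfg:
        items = []
        for i, item in enumerate(out_cfg["items"]):
            where = f"outpatient.items[{i}]"
            _check_keys(item, ("name", "unit_cost", "consumption"), where)
            for key in ("name", "unit_cost", "consumption"):
                if key not in item:
                    raise ConfigError(f"{where}: missing {key!r}")
            items.append(
                ResourceItem(
                    name=item["name"],
                    unit_cost=float(item["unit_cost"]),
                    group_consumption={
                        g: _freq_from_dict(f, f"{where}.consumption.{g}")
                        for g, f in item["consumption"].items()
                    },
                )
            )
        resource_items = tuple(items)

    mix = base.delivery_mix
    del_cfg = config.get("delivery") or {}
    _check_keys(del_cfg, ("counts", "probs", "costs"), "delivery")
    if del_cfg:
        counts = del_cfg.get("counts", mix.counts if "probs" not in del_cfg else None)
        probs = del_cfg.get("probs")
        costs = {g: dict(mix.costs[g]) for g in GROUPS}
        for g, c in (del_cfg.get("costs") or {}).items():
            if g not in GROUPS:
                raise ConfigError(f"delivery.costs: unknown group {g!r}")
            costs[g].update({str(k): float(v) for k, v in c.items()})
        if counts is not None:
            counts = {g: {str(k): int(v) for k, v in c.items()} for g, c in counts.items()}
        if probs is not None:
            probs = {g: {str(k): float(v) for k, v in p.items()} for g, p in probs.items()}
        mix = DeliveryMix(costs=costs, counts=counts, probs=probs)

    infant = base.infant_model
    inf_cfg = config.get("infant") or {}
    _check_keys(inf_cfg, ("macrosomia_prob", "conditional_probs", "outcome_costs"), "infant")
    if inf_cfg:
        macro = dict(infant.macrosomia_prob)
        macro.update(inf_cfg.get("macrosomia_prob") or {})
        cond = {g: {s: dict(v) for s, v in infant.conditional_probs[g].items()} for g in GROUPS}
        for g, strata in (inf_cfg.get("conditional_probs") or {}).items():
            if g not in GROUPS:
                raise ConfigError(f"infant.conditional_probs: unknown group {g!r}")
            for s, vec in strata.items():
                if s not in MACRO_STRATA:
                    raise ConfigError(f"infant.conditional_probs.{g}: unknown stratum {s!r}")
                cond[g][s].update(vec)
        costs = dict(infant.outcome_costs)
        costs.update(inf_cfg.get("outcome_costs") or {})
        infant = InfantOutcomeModel(
            macrosomia_prob=macro, conditional_probs=cond, outcome_costs=costs
        )

    pop_cfg = config.get("population") or {}
    _check_keys(pop_cfg, _POPULATION_KEYS, "population")

    params = ModelParameters(
        resource_items=resource_items,
        delivery_mix=mix,
        infant_model=infant,
        insulin_share=float(pop_cfg.get("insulin_share", base.insulin_share)),
        horizon_days=int(pop_cfg.get("horizon_days", base.horizon_days)),
        births=int(pop_cfg.get("births", base.births)),
        gdm_prevalence=float(pop_cfg.get("gdm_prevalence", base.gdm_prevalence)),
    )
    violations = validate(params)
    if violations:
        raise ValidationError(violations)
    return params


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a YAML parameter config; unspecified fields fall back to defaults."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parameters_from_dict(raw)
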