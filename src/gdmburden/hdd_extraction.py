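"""Parameter extraction from hospital-discharge records.

Mirrors the administrative-database procedure that populates the delivery
side of the burden model:

1. delivery admissions are the mother-role records with DRG 370-375 (other
   childbirth admissions are excluded and counted);
2. a delivery is a GDM case if ICD9-CM 648.8 (abnormal glucose tolerance in
   pregnancy) appears on the birth admission, or on any admission of the
   same patient within a 90-day look-back window — records without a
   patient ID can only be flagged via the birth admission itself;
3. the delivery mix is the per-group category counts normalised to
   probabilities;
4. per-stay costs are DRG tariffs adjusted for length of stay: within each
   category, admissions with LOS above the category's 99th percentile are
   dropped, a daily cost is the tariff divided by the mean LOS of all
   remaining women, and each group's cost is the daily cost times the
   group's mean LOS;
5. neonatal event costs are the mean reimbursement tariff over infant
   admissions carrying the event's ICD9 code(s) in any diagnosis position.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .parameters import (
    DELIVERY_CATEGORIES,
    GROUPS,
    DeliveryMix,
    ModelParameters,
    default_parameters,
)

GDM_ICD9 = "648.8"

#: ICD9-CM codes per neonatal event; codes sharing an event are pooled.
DEFAULT_COMPLICATION_CODES: Mapping[str, tuple[str, ...]] = {
    "respiratory_distress": ("769",),
    "hypoglycemia": ("775.0", "775.6"),
    "hyperbilirubinemia": ("774.2", "774.6"),
    "brachial_plexus_injury": ("767.6",),
    "shoulder_dystocia": ("660.4",),
}


@dataclass(frozen=True)
class DischargeRecord:
    """One hospital admission row (mother or infant)."""

    admission_id: str
    patient_id: str | None
    role: str  # 'mother' | 'infant'
    drg_code: str
    icd9_codes: tuple[str, ...]
    los_days: int
    admission_index: int  # days from an arbitrary epoch
    tariff: float

    def violations(self) -> list[str]:
        out = []
        if self.los_days < 1:
            out.append(f"{self.admission_id}: los_days must be >= 1")
        if not self.drg_code:
            out.append(f"{self.admission_id}: drg_code must be non-empty")
        if self.role not in ("mother", "infant"):
            out.append(f"{self.admission_id}: unknown role {self.role!r}")
        return out


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

CSV_COLUMNS = (
    "admission_id",
    "patient_id",
    "role",
    "drg",
    "icd9",
    "los_days",
    "admission_day",
    "tariff",
)


def write_records(records: Iterable[DischargeRecord], path: str | Path) -> None:
    rows = [
        {
            "admission_id": r.admission_id,
            "patient_id": r.patient_id or "",
            "role": r.role,
            "drg": r.drg_code,
            "icd9": ";".join(r.icd9_codes),
            "los_days": r.los_days,
            "admission_day": r.admission_index,
            "tariff": r.tariff,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> list[DischargeRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "drg": str, "icd9": str})
    df = df.fillna({"patient_id": "", "icd9": ""})
    return [
        DischargeRecord(
            admission_id=str(row.admission_id),
            patient_id=str(row.patient_id) or None,
            role=str(row.role),
            drg_code=str(row.drg),
            icd9_codes=tuple(c for c in str(row.icd9).split(";") if c),
            los_days=int(row.los_days),
            admission_index=int(row.admission_day),
            tariff=float(row.tariff),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# Extraction steps
# --------------------------------------------------------------------------


class DeliverySelection(NamedTuple):
    deliveries: list[DischargeRecord]
    n_excluded: int


def identify_deliveries(records: Sequence[DischargeRecord]) -> DeliverySelection:
    """Mother admissions with a delivery DRG (370-375); the rest are counted
    as excluded childbirth admissions."""
    mothers = [r for r in records if r.role == "mother"]
    deliveries = [r for r in mothers if r.drg_code in DELIVERY_CATEGORIES]
    return DeliverySelection(deliveries, len(mothers) - len(deliveries))


def flag_gdm(
    records: Sequence[DischargeRecord],
    delivery_subset: Sequence[DischargeRecord],
    lookback_days: int = 90,
) -> dict[str, bool]:
    """GDM status per delivery admission.

    A delivery is GDM if 648.8 is coded on the admission itself, or on any
    admission of the same patient strictly before it and at most
    ``lookback_days`` days earlier.  Deliveries without a patient ID cannot
    be linked and rely on the birth admission alone.
    """
    gdm_days_by_patient: dict[str, list[int]] = defaultdict(list)
    for r in records:
        if r.patient_id is not None and GDM_ICD9 in r.icd9_codes:
            gdm_days_by_patient[r.patient_id].append(r.admission_index)

    flags = {}
    for d in delivery_subset:
        flagged = GDM_ICD9 in d.icd9_codes
        if not flagged and d.patient_id is not None:
            flagged = any(
                0 < d.admission_index - day <= lookback_days
                for day in gdm_days_by_patient.get(d.patient_id, ())
            )
        flags[d.admission_id] = flagged
    return flags


def _group_of(record: DischargeRecord, gdm_flags: Mapping[str, bool]) -> str:
    return "gdm" if gdm_flags[record.admission_id] else "euglycemia"


class DeliveryMixEstimate(NamedTuple):
    probs: dict[str, dict[str, float]]  # group -> drg -> probability
    counts: dict[str, dict[str, int]]


def estimate_delivery_mix(
    delivery_subset: Sequence[DischargeRecord], gdm_flags: Mapping[str, bool]
) -> DeliveryMixEstimate:
    """Per-group category counts normalised to probabilities."""
    counts = {g: {d: 0 for d in DELIVERY_CATEGORIES} for g in GROUPS}
    for r in delivery_subset:
        counts[_group_of(r, gdm_flags)][r.drg_code] += 1
    probs = {}
    for g in GROUPS:
        total = sum(counts[g].values())
        if total == 0:
            raise ValueError(f"no deliveries in group {g!r}")
        probs[g] = {d: counts[g][d] / total for d in DELIVERY_CATEGORIES}
    return DeliveryMixEstimate(probs, counts)


def _nearest_rank_percentile(sorted_values: Sequence[int], q: float) -> int:
    n = len(sorted_values)
    rank = max(1, math.ceil(q * n))
    return sorted_values[rank - 1]


class LOSCostResult(NamedTuple):
    costs: dict[str, dict[str, float]]  # group -> drg -> money
    group_los: dict[str, dict[str, float]]  # group -> drg -> mean LOS (post-trim)
    excluded_outliers: int


def los_adjusted_cost(
    delivery_subset: Sequence[DischargeRecord],
    gdm_flags: Mapping[str, bool],
    tariffs: Mapping[str, float],
    outlier_quantile: float = 0.99,
) -> LOSCostResult:
    """LOS-adjusted per-stay cost per group and delivery category.

    Outliers (LOS strictly above the category's nearest-rank percentile,
    computed over all women in the category) are excluded first.
    """
    by_cat: dict[str, list[DischargeRecord]] = defaultdict(list)
    for r in delivery_subset:
        by_cat[r.drg_code].append(r)

    costs: dict[str, dict[str, float]] = {g: {} for g in GROUPS}
    group_los: dict[str, dict[str, float]] = {g: {} for g in GROUPS}
    excluded = 0
    for drg in DELIVERY_CATEGORIES:
        cat = by_cat.get(drg, [])
        if not cat:
            raise ValueError(f"no admissions in delivery category {drg}")
        threshold = _nearest_rank_percentile(
            sorted(r.los_days for r in cat), outlier_quantile
        )
        kept = [r for r in cat if r.los_days <= threshold]
        excluded += len(cat) - len(kept)
        overall_mean = sum(r.los_days for r in kept) / len(kept)
        daily_cost = tariffs[drg] / overall_mean
        for g in GROUPS:
            group_records = [r for r in kept if _group_of(r, gdm_flags) == g]
            if not group_records:
                raise ValueError(
                    f"category {drg}: no non-outlier admissions in group {g!r}"
                )
            mean_los = sum(r.los_days for r in group_records) / len(group_records)
            group_los[g][drg] = mean_los
            costs[g][drg] = daily_cost * mean_los
    return LOSCostResult(costs, group_los, excluded)


def infant_event_costs(
    infant_records: Sequence[DischargeRecord],
    complication_codes: Mapping[str, tuple[str, ...]] = DEFAULT_COMPLICATION_CODES,
) -> dict[str, float]:
    """Mean reimbursement tariff per neonatal event.

    An admission contributes to every event whose code it carries (any
    diagnosis position); codes mapped to the same event are pooled.  Events
    with no admissions are omitted (missing, not zero).
    """
    out = {}
    for event, codes in complication_codes.items():
        tariffs = [
            r.tariff
            for r in infant_records
            if any(c in r.icd9_codes for c in codes)
        ]
        if tariffs:
            out[event] = sum(tariffs) / len(tariffs)
    return out


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionResult:
    delivery_mix: DeliveryMix  # estimated probabilities + LOS-adjusted costs
    group_los: dict[str, dict[str, float]]
    gdm_flags: dict[str, bool]
    excluded_outliers: int
    n_excluded_deliveries: int
    infant_event_costs: dict[str, float]


def extract(
    mother_records: Sequence[DischargeRecord],
    tariffs: Mapping[str, float],
    infant_records: Sequence[DischargeRecord] = (),
    lookback_days: int = 90,
    outlier_quantile: float = 0.99,
) -> ExtractionResult:
    """Run the whole extraction: identify, flag, estimate, cost."""
    deliveries, n_excluded = identify_deliveries(mother_records)
    flags = flag_gdm(mother_records, deliveries, lookback_days)
    mix = estimate_delivery_mix(deliveries, flags)
    los_result = los_adjusted_cost(deliveries, flags, tariffs, outlier_quantile)
    return ExtractionResult(
        delivery_mix=DeliveryMix(costs=los_result.costs, counts=mix.counts),
        group_los=los_result.group_los,
        gdm_flags=flags,
        excluded_outliers=los_result.excluded_outliers,
        n_excluded_deliveries=n_excluded,
        infant_event_costs=infant_event_costs(infant_records)
        if infant_records
        else {},
    )


def parameters_from_extraction(
    result: ExtractionResult, base: ModelParameters | None = None
) -> ModelParameters:
    """Close the loop: a model parameter set whose delivery side comes from
    the extracted records.

    Neonatal outcome *probabilities* always stay literature-derived (the
    database cannot link infants to mothers); extracted event costs replace
    the base ones where available.
    """
    base = base if base is not None else default_parameters()
    outcome_costs = dict(base.infant_model.outcome_costs)
    outcome_costs.update(result.infant_event_costs)
    return replace(
        base,
        delivery_mix=result.delivery_mix,
        infant_model=replace(base.infant_model, outcome_costs=outcome_costs),
    )
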