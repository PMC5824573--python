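"""Synthetic hospital-discharge cohorts for exercising the extraction pipeline.

No real discharge database is distributable, so this module generates
mother and infant admission records with the statistical structure the
extraction procedure assumes: a Bernoulli GDM status at the configured
prevalence, a per-group multinomial delivery DRG, an over-dispersed
integer length of stay (1 + negative binomial, so the 99th-percentile
outlier filter has a real tail to bite on), GDM coding either on the birth
record or only on a linked prior admission inside the 90-day look-back
window, a configurable fraction of records without a patient ID, and
infant records carrying neonatal complication ICD9 codes with tariffs
drawn around configured means.

:func:`calibrated_cohort_spec` returns the cohort specification whose
generating parameters match the packaged Italian 2014 model inputs: the
delivery-mix count ratios, the 9.1% missing-ID rate, and LOS/tariff
settings calibrated so that the LOS-adjusted costing recovers the packaged
per-stay delivery costs in expectation (the calibration works on the
post-outlier-filter trimmed expectations, so the filter introduces no bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .hdd_extraction import (
    DEFAULT_COMPLICATION_CODES,
    GDM_ICD9,
    DischargeRecord,
)
from .parameters import (
    DELIVERY_CATEGORIES,
    GROUPS,
    INFANT_OUTCOMES,
    default_parameters,
)

# Non-delivery DRG used for generated look-back admissions (other antepartum
# diagnoses) and a routine birth code for clean records.
_LOOKBACK_DRG = "383"
_BIRTH_ICD9 = "V27.0"
_INFANT_BIRTH_ICD9 = "V30.0"


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of one synthetic cohort.

    los_distribution maps group -> DRG -> (mean_days, dispersion); LOS is
    drawn as 1 + NegativeBinomial with that mean and size (dispersion)
    parameter.  tariffs maps a delivery DRG to the official per-stay tariff
    and a neonatal event name to the mean reimbursement of admissions
    carrying that event's codes.
    """

    n_mothers: int
    gdm_prevalence: float
    delivery_probs: Mapping[str, Mapping[str, float]]
    los_distribution: Mapping[str, Mapping[str, tuple[float, float]]]
    tariffs: Mapping[str, float]
    infant_complication_rates: Mapping[str, float]
    lookback_flag_fraction: float = 0.25
    missing_id_fraction: float = 0.091
    infant_missing_id_fraction: float = 1.0 / 3.0
    infant_cost_cv: float = 0.2
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.n_mothers <= 0:
            out.append("n_mothers must be > 0")
        for name, p in (
            ("gdm_prevalence", self.gdm_prevalence),
            ("lookback_flag_fraction", self.lookback_flag_fraction),
            ("missing_id_fraction", self.missing_id_fraction),
            ("infant_missing_id_fraction", self.infant_missing_id_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                out.append(f"{name}: {p} outside [0, 1]")
        for g in GROUPS:
            probs = self.delivery_probs.get(g)
            if probs is None:
                out.append(f"delivery_probs[{g}]: missing")
                continue
            total = sum(probs.get(d, 0.0) for d in DELIVERY_CATEGORIES)
            if abs(total - 1.0) > 1e-9:
                out.append(f"delivery_probs[{g}]: sum {total:.6f}, not 1")
            for d in DELIVERY_CATEGORIES:
                mean, size = self.los_distribution[g][d]
                if mean < 1.0 or size <= 0:
                    out.append(f"los_distribution[{g}][{d}]: need mean >= 1, size > 0")
        for d in DELIVERY_CATEGORIES:
            if d not in self.tariffs:
                out.append(f"tariffs[{d}]: missing")
        for event, rate in self.infant_complication_rates.items():
            if not 0.0 <= rate <= 1.0:
                out.append(f"infant_complication_rates[{event}]: {rate} outside [0, 1]")
        return out

    def _require_valid(self) -> None:
        violations = self.violations()
        if violations:
            raise ValueError("invalid CohortSpec:\n  " + "\n  ".join(violations))


def _draw_los(
    rng: np.random.Generator, mean: float, size_param: float, n: int
) -> np.ndarray:
    """1 + NB(mean - 1, size); mean of the draw equals `mean`."""
    m = mean - 1.0
    if m <= 0 or n == 0:
        return np.ones(n, dtype=int)
    p = size_param / (size_param + m)
    return 1 + rng.negative_binomial(size_param, p, size=n)


def generate_mothers(spec: CohortSpec) -> list[DischargeRecord]:
    """Delivery admissions (plus look-back admissions for the GDM mothers
    coded only before delivery), seeded and reproducible."""
    spec._require_valid()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_mothers

    is_gdm = rng.random(n) < spec.gdm_prevalence
    category = np.empty(n, dtype=int)
    for g, mask in (("euglycemia", ~is_gdm), ("gdm", is_gdm)):
        probs = [spec.delivery_probs[g][d] for d in DELIVERY_CATEGORIES]
        category[mask] = rng.choice(len(DELIVERY_CATEGORIES), size=int(mask.sum()), p=probs)

    los = np.empty(n, dtype=int)
    for gi, g in enumerate(GROUPS):
        gmask = is_gdm if g == "gdm" else ~is_gdm
        for ci, d in enumerate(DELIVERY_CATEGORIES):
            mask = gmask & (category == ci)
            mean, size_param = spec.los_distribution[g][d]
            los[mask] = _draw_los(rng, mean, size_param, int(mask.sum()))

    birth_day = rng.integers(100, 465, size=n)
    missing_id = rng.random(n) < spec.missing_id_fraction
    lookback_only = is_gdm & (rng.random(n) < spec.lookback_flag_fraction)
    lookback_lag = rng.integers(1, 91, size=n)  # days before delivery, 1..90

    records: list[DischargeRecord] = []
    for i in range(n):
        drg = DELIVERY_CATEGORIES[category[i]]
        patient_id = None if missing_id[i] else f"P{i:07d}"
        icd9: tuple[str, ...] = (_BIRTH_ICD9,)
        if is_gdm[i] and not lookback_only[i]:
            icd9 = (_BIRTH_ICD9, GDM_ICD9)
        records.append(
            DischargeRecord(
                admission_id=f"M{i:07d}",
                patient_id=patient_id,
                role="mother",
                drg_code=drg,
                icd9_codes=icd9,
                los_days=int(los[i]),
                admission_index=int(birth_day[i]),
                tariff=float(spec.tariffs[drg]),
            )
        )
        if is_gdm[i] and lookback_only[i]:
            records.append(
                DischargeRecord(
                    admission_id=f"L{i:07d}",
                    patient_id=patient_id,
                    role="mother",
                    drg_code=_LOOKBACK_DRG,
                    icd9_codes=(GDM_ICD9,),
                    los_days=2,
                    admission_index=int(birth_day[i] - lookback_lag[i]),
                    tariff=500.0,
                )
            )
    return records


def generate_infants(spec: CohortSpec) -> list[DischargeRecord]:
    """Infant birth admissions carrying complication codes at the spec'd
    incidences; deliberately unlinkable to the mothers.

    Events are drawn as one categorical outcome per infant (mutually
    exclusive, mirroring the outcome model), so the mean tariff over the
    admissions carrying a code is an unbiased estimate of that event's
    configured tariff."""
    spec._require_valid()
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_mothers

    events = [e for e in spec.infant_complication_rates if e in DEFAULT_COMPLICATION_CODES]
    rates = np.array([spec.infant_complication_rates[e] for e in events])
    if rates.sum() > 1.0:
        raise ValueError("infant complication rates sum above 1")
    outcome = rng.choice(len(events) + 1, size=n, p=[1.0 - rates.sum(), *rates])
    # which of the pooled ICD9 codes a flagged infant carries
    code_pick = rng.integers(
        0, max(len(DEFAULT_COMPLICATION_CODES[e]) for e in events) if events else 1, size=n
    )
    missing_id = rng.random(n) < spec.infant_missing_id_fraction
    los = _draw_los(rng, 3.0, 5.0, n)
    noise = rng.gamma(
        1.0 / spec.infant_cost_cv**2, spec.infant_cost_cv**2, size=n
    )  # unit-mean multiplicative tariff noise

    normal_cost = spec.tariffs.get("normal_newborn", 560.0)
    records = []
    for i in range(n):
        codes = [_INFANT_BIRTH_ICD9]
        if outcome[i] == 0:
            basis, drg = normal_cost, "391"
        else:
            event = events[outcome[i] - 1]
            pooled = DEFAULT_COMPLICATION_CODES[event]
            codes.append(pooled[code_pick[i] % len(pooled)])
            basis, drg = spec.tariffs[event], "390"
        records.append(
            DischargeRecord(
                admission_id=f"I{i:07d}",
                patient_id=None if missing_id[i] else f"N{i:07d}",
                role="infant",
                drg_code=drg,
                icd9_codes=tuple(codes),
                los_days=int(los[i]),
                admission_index=int(rng.integers(100, 465)),
                tariff=float(basis * noise[i]),
            )
        )
    return records


# --------------------------------------------------------------------------
# Calibration to the packaged model inputs
# --------------------------------------------------------------------------

# Plausible mean delivery LOS (days) for euglycemic women by DRG: caesarean
# stays run longer than vaginal ones, complications add days.
_BASE_LOS_EUGLYCEMIA = {
    "370": 6.0,
    "371": 5.0,
    "372": 4.0,
    "373": 3.0,
    "374": 3.5,
    "375": 4.0,
}
_LOS_DISPERSION = 8.0  # negative-binomial size; smaller = heavier tail


def _trimmed_los_stats(mean: float, size_param: float, threshold: int):
    """(partial expectation, retained probability) of LOS = 1 + NB, LOS <= threshold."""
    m = mean - 1.0
    if m <= 0:
        return (1.0, 1.0) if threshold >= 1 else (0.0, 0.0)
    dist = stats.nbinom(size_param, size_param / (size_param + m))
    k = np.arange(0, threshold)  # LOS = k + 1
    pmf = dist.pmf(k)
    return float(np.sum((k + 1) * pmf)), float(dist.cdf(threshold - 1))


def _pooled_threshold(
    mu_e: float, mu_g: float, size_param: float, w_e: float, w_g: float, q: float
) -> int:
    """Smallest integer LOS t with pooled CDF >= q."""
    for t in range(1, 10_000):
        cdf = 0.0
        for mu, w in ((mu_e, w_e), (mu_g, w_g)):
            m = mu - 1.0
            if m <= 0:
                cdf += w
            else:
                dist = stats.nbinom(size_param, size_param / (size_param + m))
                cdf += w * dist.cdf(t - 1)
        if cdf >= q:
            return t
    raise RuntimeError("LOS threshold search did not converge")


def _calibrate_category(
    mu_e: float,
    size_param: float,
    cost_e: float,
    cost_g: float,
    w_e: float,
    w_g: float,
    q: float = 0.99,
) -> tuple[float, float]:
    """Solve for the GDM mean LOS and the tariff of one delivery category.

    After the outlier filter, the expected group cost is
    tariff * trimmed_mean(group) / trimmed_mean(all); the GDM mean is chosen
    so the trimmed-mean ratio equals cost_g / cost_e, and the tariff so the
    euglycemia cost equals cost_e exactly.
    """

    def ratio_gap(mu_g: float) -> float:
        t = _pooled_threshold(mu_e, mu_g, size_param, w_e, w_g, q)
        pe, ke = _trimmed_los_stats(mu_e, size_param, t)
        pg, kg = _trimmed_los_stats(mu_g, size_param, t)
        return (pg / kg) / (pe / ke) - cost_g / cost_e

    mu_g = optimize.brentq(ratio_gap, mu_e * 0.5, mu_e * 4.0, xtol=1e-10)
    t = _pooled_threshold(mu_e, mu_g, size_param, w_e, w_g, q)
    pe, ke = _trimmed_los_stats(mu_e, size_param, t)
    pg, kg = _trimmed_los_stats(mu_g, size_param, t)
    pooled_mean = (w_e * pe + w_g * pg) / (w_e * ke + w_g * kg)
    tariff = cost_e * pooled_mean / (pe / ke)
    return mu_g, tariff


@lru_cache(maxsize=4)
def _calibrated_los_and_tariffs(
    outlier_quantile: float = 0.99,
) -> tuple[dict, dict]:
    params = default_parameters()
    mix = params.delivery_mix
    prev = params.gdm_prevalence
    los = {g: {} for g in GROUPS}
    tariffs = {}
    for d in DELIVERY_CATEGORIES:
        w_e = (1.0 - prev) * mix.probability("euglycemia", d)
        w_g = prev * mix.probability("gdm", d)
        total = w_e + w_g
        mu_e = _BASE_LOS_EUGLYCEMIA[d]
        mu_g, tariff = _calibrate_category(
            mu_e,
            _LOS_DISPERSION,
            mix.cost("euglycemia", d),
            mix.cost("gdm", d),
            w_e / total,
            w_g / total,
            outlier_quantile,
        )
        los["euglycemia"][d] = (mu_e, _LOS_DISPERSION)
        los["gdm"][d] = (mu_g, _LOS_DISPERSION)
        tariffs[d] = tariff
    return los, tariffs


def marginal_complication_rates() -> dict[str, float]:
    """Population-level incidence of each neonatal event implied by the
    packaged outcome model at the packaged prevalence."""
    params = default_parameters()
    infant = params.infant_model
    rates = {o: 0.0 for o in INFANT_OUTCOMES if o != "normal_newborn"}
    weights = {"gdm": params.gdm_prevalence, "euglycemia": 1.0 - params.gdm_prevalence}
    for g, w in weights.items():
        p_macro = infant.macrosomia_prob[g]
        for stratum, sw in (("macrosomia", p_macro), ("no_macrosomia", 1.0 - p_macro)):
            vec = infant.conditional_probs[g][stratum]
            for o in rates:
                rates[o] += w * sw * vec[o]
    return rates


def calibrated_cohort_spec(n_mothers: int = 100_000, seed: int = 0) -> CohortSpec:
    """Cohort spec whose generating parameters match the packaged model:
    delivery-mix count ratios, 9.1% missing mother IDs, neonatal event
    incidences implied by the outcome model, event tariffs equal to the
    packaged event costs, and LOS/tariff settings calibrated so that the
    LOS-adjusted costing recovers the packaged delivery costs in
    expectation."""
    params = default_parameters()
    los, tariffs = _calibrated_los_and_tariffs()
    tariffs = dict(tariffs)
    tariffs.update(params.infant_model.outcome_costs)  # events + normal_newborn
    return CohortSpec(
        n_mothers=n_mothers,
        gdm_prevalence=params.gdm_prevalence,
        delivery_probs={
            g: params.delivery_mix.probability_vector(g) for g in GROUPS
        },
        los_distribution=los,
        tariffs=tariffs,
        infant_complication_rates=marginal_complication_rates(),
        seed=seed,
    )
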