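"""Deterministic and probabilistic sensitivity analysis.

One-way (deterministic) analysis multiplies a single cost or probability by
(1 + rel_change) — conventionally +/-20% — and recomputes the inpatient cost
per case for both glycemic groups.  When a conditional neonatal outcome
probability is perturbed, the normal-newborn complement absorbs the change
so the outcome vector still sums to one.

Probabilistic sensitivity analysis draws every probability and cost from a
parametric distribution and recomputes the inpatient cost per case per
iteration: multinomial probability vectors from a Dirichlet (each marginal
is a beta) built from admission counts where counts exist, or from
moment-matched pseudo-counts where only point probabilities exist; costs
from gamma distributions moment-matched to the base value with a configured
coefficient of variation.  Outpatient costs are tariff-listed constants and
are excluded from both analyses.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .parameters import (
    CATEGORY_LABELS,
    DELIVERY_CATEGORIES,
    GROUPS,
    INFANT_OUTCOMES,
    LABEL_TO_CATEGORY,
    MACRO_STRATA,
    DeliveryMix,
    InfantOutcomeModel,
    ModelParameters,
)
from .tree_model import infant_inpatient_cost, mother_inpatient_cost

_NAMED_COMPLICATIONS = tuple(o for o in INFANT_OUTCOMES if o != "normal_newborn")


# --------------------------------------------------------------------------
# One-way (deterministic) sensitivity analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DSAResult:
    """Inpatient cost per case for both groups after one perturbation."""

    parameter_id: str
    rel_change: float
    cost_per_case_euglycemia: float
    cost_per_case_gdm: float

    @property
    def delta(self) -> float:
        return self.cost_per_case_gdm - self.cost_per_case_euglycemia


class DSAPair(NamedTuple):
    """Low/high results of one parameter varied symmetrically."""

    parameter_id: str
    low: DSAResult
    high: DSAResult

    @property
    def delta_range(self) -> float:
        return abs(self.high.delta - self.low.delta)


def dsa_parameter_ids() -> list[str]:
    """The one-way analysis vocabulary: every inpatient cost and every
    literature-derived neonatal probability in the model."""
    ids = [f"cost:{CATEGORY_LABELS[d]}:{g}" for g in GROUPS for d in DELIVERY_CATEGORIES]
    ids += [f"cost:{o}" for o in INFANT_OUTCOMES]
    ids += [f"prob:macrosomia:{g}" for g in GROUPS]
    ids += [
        f"prob:{o}:{g}:{s}"
        for g in GROUPS
        for s in MACRO_STRATA
        for o in _NAMED_COMPLICATIONS
    ]
    return ids


def _perturbed(params: ModelParameters, parameter_id: str, rel_change: float) -> ModelParameters:
    parts = parameter_id.split(":")
    factor = 1.0 + rel_change
    mix, infant = params.delivery_mix, params.infant_model

    if parts[0] == "cost" and len(parts) == 3 and parts[1] in LABEL_TO_CATEGORY:
        label, group = parts[1], parts[2]
        if group not in GROUPS:
            raise ValueError(f"unknown group in {parameter_id!r}")
        drg = LABEL_TO_CATEGORY[label]
        costs = {g: dict(mix.costs[g]) for g in GROUPS}
        costs[group][drg] *= factor
        return replace(params, delivery_mix=replace(mix, costs=costs))

    if parts[0] == "cost" and len(parts) == 2 and parts[1] in INFANT_OUTCOMES:
        costs = dict(infant.outcome_costs)
        costs[parts[1]] *= factor
        return replace(params, infant_model=replace(infant, outcome_costs=costs))

    if parts[0] == "prob" and parts[1] == "macrosomia" and len(parts) == 3:
        group = parts[2]
        if group not in GROUPS:
            raise ValueError(f"unknown group in {parameter_id!r}")
        macro = dict(infant.macrosomia_prob)
        macro[group] *= factor
        if not 0.0 <= macro[group] <= 1.0:
            raise ValueError(
                f"{parameter_id}: perturbed probability {macro[group]:.4f} outside [0, 1]"
            )
        return replace(params, infant_model=replace(infant, macrosomia_prob=macro))

    if parts[0] == "prob" and len(parts) == 4 and parts[1] in _NAMED_COMPLICATIONS:
        outcome, group, stratum = parts[1], parts[2], parts[3]
        if group not in GROUPS or stratum not in MACRO_STRATA:
            raise ValueError(f"unknown group/stratum in {parameter_id!r}")
        cond = {
            g: {s: dict(v) for s, v in infant.conditional_probs[g].items()}
            for g in GROUPS
        }
        vec = cond[group][stratum]
        old = vec[outcome]
        new = old * factor
        if not 0.0 <= new <= 1.0:
            raise ValueError(
                f"{parameter_id}: perturbed probability {new:.4f} outside [0, 1]"
            )
        # the normal-newborn complement absorbs the change
        normal = vec["normal_newborn"] - (new - old)
        if normal < 0.0:
            raise ValueError(
                f"{parameter_id}: normal-newborn complement {normal:.4f} below 0"
            )
        vec[outcome] = new
        vec["normal_newborn"] = normal
        return replace(params, infant_model=replace(infant, conditional_probs=cond))

    raise ValueError(
        f"unknown parameter_id {parameter_id!r}; valid ids: {dsa_parameter_ids()}"
    )


def _inpatient_cost(params: ModelParameters, group: str) -> float:
    return mother_inpatient_cost(params.delivery_mix, group) + infant_inpatient_cost(
        params.infant_model, group
    )


def one_way(params: ModelParameters, parameter_id: str, rel_change: float) -> DSAResult:
    """Recompute both groups' inpatient cost per case with one parameter
    multiplied by (1 + rel_change)."""
    perturbed = _perturbed(params, parameter_id, rel_change)
    return DSAResult(
        parameter_id=parameter_id,
        rel_change=rel_change,
        cost_per_case_euglycemia=_inpatient_cost(perturbed, "euglycemia"),
        cost_per_case_gdm=_inpatient_cost(perturbed, "gdm"),
    )


def tornado(
    params: ModelParameters, parameter_ids: Sequence[str], rel_change: float = 0.2
) -> list[DSAPair]:
    """Symmetric +/-rel_change on each parameter, ranked by impact on the
    GDM-euglycemia cost difference (widest range first)."""
    pairs = [
        DSAPair(pid, one_way(params, pid, -rel_change), one_way(params, pid, +rel_change))
        for pid in parameter_ids
    ]
    return sorted(pairs, key=lambda p: p.delta_range, reverse=True)


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


class BetaParams(NamedTuple):
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


class GammaParams(NamedTuple):
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def beta_from_counts(successes: float, total: float) -> BetaParams:
    """Beta(successes, failures) — the count-based parameterization whose
    mean is the observed proportion.  Zero successes (or failures) gives a
    degenerate shape of 0, which samplers treat as a point mass."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= successes <= total:
        raise ValueError("need 0 <= successes <= total")
    return BetaParams(float(successes), float(total - successes))


def beta_from_moments(mean: float, sd: float) -> BetaParams:
    """Moment-matched beta with the given mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"sd {sd} too large for a beta with mean {mean}")
    return BetaParams(mean * nu, (1.0 - mean) * nu)


def gamma_from_moments(mean: float, cv: float) -> GammaParams:
    """Moment-matched gamma: shape = 1/cv^2, scale = mean * cv^2."""
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be > 0")
    return GammaParams(shape=1.0 / cv**2, scale=mean * cv**2)


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings.

    cost_cv: coefficient of variation for every gamma-distributed cost.
    prob_se_frac: relative standard error assumed for probabilities that are
        published only as point values (the neonatal outcome model).
    probability_source: 'counts' uses Dirichlet distributions built from the
        stored admission counts for the delivery mix; 'moments' moment-matches
        pseudo-counts from prob_se_frac instead.
    infant_sampling: 'dirichlet' draws each conditional outcome vector
        jointly; 'independent' draws each named complication as its own beta
        with the normal-newborn entry taking the complement.
    """

    n_iterations: int = 1000
    seed: int = 0
    cost_cv: float = 0.2
    prob_se_frac: float = 0.2
    probability_source: str = "counts"
    infant_sampling: str = "dirichlet"

    def __post_init__(self):
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be > 0")
        if self.cost_cv <= 0 or self.prob_se_frac <= 0:
            raise ValueError("cost_cv and prob_se_frac must be > 0")
        if self.probability_source not in ("counts", "moments"):
            raise ValueError("probability_source must be 'counts' or 'moments'")
        if self.infant_sampling not in ("dirichlet", "independent"):
            raise ValueError("infant_sampling must be 'dirichlet' or 'independent'")


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration inpatient cost-per-case draws and their summaries."""

    draws: dict[str, np.ndarray]  # 'euglycemia', 'gdm', 'delta'
    summaries: dict[str, dict[str, float]]
    config: PSAConfig


def _summary(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def _dirichlet_alphas_from_moments(means: np.ndarray, se_frac: float) -> np.ndarray:
    # Concentration chosen by moment-matching each component's beta marginal
    # (sd = se_frac * mean) and taking the median implied concentration.
    nus = (1.0 - means) / (se_frac**2 * means) - 1.0
    nu = float(np.median(nus[nus > 0]))
    return means * nu


def _draw_prob_vectors(
    rng: np.random.Generator, means: np.ndarray, alphas: np.ndarray, n: int
) -> np.ndarray:
    if np.all(alphas > 0):
        return rng.dirichlet(alphas, size=n)
    # degenerate components (zero pseudo-count) are point masses at 0
    out = np.zeros((n, means.size))
    live = alphas > 0
    out[:, live] = rng.dirichlet(alphas[live], size=n)
    return out


def run_psa(params: ModelParameters, config: PSAConfig) -> PSAResult:
    """Monte Carlo over all inpatient probabilities and costs.

    Draw order is fixed (delivery probabilities, delivery costs, macrosomia,
    conditional outcome vectors, outcome costs; euglycemia before GDM) so a
    given seed always reproduces the same draws.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    mix, infant = params.delivery_mix, params.infant_model

    delivery_probs: dict[str, np.ndarray] = {}
    for g in GROUPS:
        means = np.array([mix.probability(g, d) for d in DELIVERY_CATEGORIES])
        if config.probability_source == "counts" and mix.counts is not None:
            alphas = np.array([float(mix.counts[g][d]) for d in DELIVERY_CATEGORIES])
        else:
            alphas = _dirichlet_alphas_from_moments(means, config.prob_se_frac)
        delivery_probs[g] = _draw_prob_vectors(rng, means, alphas, n)

    delivery_costs: dict[str, np.ndarray] = {}
    for g in GROUPS:
        cols = []
        for d in DELIVERY_CATEGORIES:
            gp = gamma_from_moments(mix.cost(g, d), config.cost_cv)
            cols.append(rng.gamma(gp.shape, gp.scale, size=n))
        delivery_costs[g] = np.column_stack(cols)

    macro: dict[str, np.ndarray] = {}
    for g in GROUPS:
        bp = beta_from_moments(
            infant.macrosomia_prob[g], config.prob_se_frac * infant.macrosomia_prob[g]
        )
        macro[g] = rng.beta(bp.alpha, bp.beta, size=n)

    cond: dict[str, dict[str, np.ndarray]] = {g: {} for g in GROUPS}
    for g in GROUPS:
        for stratum in MACRO_STRATA:
            vec = infant.conditional_probs[g][stratum]
            means = np.array([vec[o] for o in INFANT_OUTCOMES])
            if config.infant_sampling == "dirichlet":
                alphas = _dirichlet_alphas_from_moments(
                    means[:-1], config.prob_se_frac
                )
                # give the closing complement its mean-proportional share of
                # the same concentration
                nu = alphas.sum() / means[:-1].sum()
                alphas = np.append(alphas, means[-1] * nu)
                draws = _draw_prob_vectors(rng, means, alphas, n)
            else:
                cols = [
                    rng.beta(*beta_from_moments(m, config.prob_se_frac * m), size=n)
                    for m in means[:-1]
                ]
                named = np.column_stack(cols)
                normal = np.clip(1.0 - named.sum(axis=1), 0.0, None)
                draws = np.column_stack([named, normal])
                draws /= draws.sum(axis=1, keepdims=True)
            cond[g][stratum] = draws

    outcome_cols = []
    for o in INFANT_OUTCOMES:
        gp = gamma_from_moments(infant.outcome_costs[o], config.cost_cv)
        outcome_cols.append(rng.gamma(gp.shape, gp.scale, size=n))
    outcome_costs = np.column_stack(outcome_cols)

    draws = {}
    for g in GROUPS:
        mother = np.sum(delivery_probs[g] * delivery_costs[g], axis=1)
        infant_ev = macro[g] * np.sum(cond[g]["macrosomia"] * outcome_costs, axis=1) + (
            1.0 - macro[g]
        ) * np.sum(cond[g]["no_macrosomia"] * outcome_costs, axis=1)
        draws[g] = mother + infant_ev
    draws["delta"] = draws["gdm"] - draws["euglycemia"]

    return PSAResult(
        draws=draws,
        summaries={k: _summary(v) for k, v in draws.items()},
        config=config,
    )
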