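import numpy as np
import pytest

from gdmburden.parameters import LABEL_TO_CATEGORY
from gdmburden.sensitivity import (
    PSAConfig,
    beta_from_counts,
    beta_from_moments,
    dsa_parameter_ids,
    gamma_from_moments,
    one_way,
    run_psa,
    tornado,
)
from gdmburden.tree_model import infant_inpatient_cost, mother_inpatient_cost


def _base_inpatient(params, group):
    return mother_inpatient_cost(params.delivery_mix, group) + infant_inpatient_cost(
        params.infant_model, group
    )


def test_zero_change_reproduces_base_case(params):
    r = one_way(params, "cost:hypoglycemia", 0.0)
    assert r.cost_per_case_euglycemia == pytest.approx(_base_inpatient(params, "euglycemia"))
    assert r.cost_per_case_gdm == pytest.approx(_base_inpatient(params, "gdm"))


def test_unknown_parameter_lists_valid_ids(params):
    with pytest.raises(ValueError, match="cost:caesarean_without_cc:gdm"):
        one_way(params, "cost:nonexistent_thing", 0.2)


def test_probability_perturbation_out_of_range_is_an_error(params):
    # 0.104 * 21 > 1: the perturbed probability leaves [0, 1]
    with pytest.raises(ValueError, match="outside"):
        one_way(params, "prob:hyperbilirubinemia:gdm:no_macrosomia", 20.0)
    # 0.132 * 6 stays in [0, 1] but exceeds the 0.644 normal complement
    with pytest.raises(ValueError, match="normal-newborn"):
        one_way(params, "prob:hyperbilirubinemia:gdm:macrosomia", 5.0)


def test_gdm_only_parameter_leaves_euglycemia_at_base(params):
    base = _base_inpatient(params, "euglycemia")
    r = one_way(params, "cost:caesarean_without_cc:gdm", -0.2)
    assert r.cost_per_case_euglycemia == pytest.approx(base)
    assert r.delta == pytest.approx(r.cost_per_case_gdm - r.cost_per_case_euglycemia)


@pytest.mark.parametrize(
    "pid, group",
    [
        ("cost:caesarean_without_cc:gdm", "gdm"),
        ("cost:vaginal_without_cc:euglycemia", "euglycemia"),
    ],
)
def test_cost_response_is_affine_with_the_exposure_weight(params, pid, group):
    """Perturbing a delivery cost c by +/-20% moves that group's expected
    cost by exactly +/-0.2 * c * P(category)."""
    label = pid.split(":")[1]
    drg = LABEL_TO_CATEGORY[label]
    weight = params.delivery_mix.probability(group, drg)
    c = params.delivery_mix.cost(group, drg)
    base = _base_inpatient(params, group)
    for rel in (-0.2, 0.2):
        r = one_way(params, pid, rel)
        got = r.cost_per_case_gdm if group == "gdm" else r.cost_per_case_euglycemia
        assert got - base == pytest.approx(rel * c * weight, abs=1e-9)


def test_tornado_ranks_by_delta_range(params):
    ids = ["cost:caesarean_without_cc:gdm", "cost:hypoglycemia", "cost:normal_newborn"]
    pairs = tornado(params, ids, 0.2)
    ranges = [p.delta_range for p in pairs]
    assert ranges == sorted(ranges, reverse=True)
    assert pairs[0].parameter_id == "cost:caesarean_without_cc:gdm"
    assert tornado(params, [], 0.2) == []
    assert len(tornado(params, ["cost:hypoglycemia"], 0.2)) == 1
    assert len(dsa_parameter_ids()) == 40


def test_beta_from_counts():
    bp = beta_from_counts(4019, 11434)
    assert (bp.alpha, bp.beta) == (4019, 7415)
    assert bp.mean == pytest.approx(0.3515, abs=5e-5)
    assert beta_from_counts(0, 10).alpha == 0.0  # point mass at 0
    assert beta_from_counts(10, 10).beta == 0.0  # point mass at 1
    with pytest.raises(ValueError):
        beta_from_counts(1, 0)


def test_gamma_from_moments():
    gp = gamma_from_moments(560.0, 0.2)
    assert gp.shape == pytest.approx(25.0)
    assert gp.scale == pytest.approx(22.4)
    rng = np.random.default_rng(7)
    samples = rng.gamma(gp.shape, gp.scale, size=100_000)
    assert samples.mean() == pytest.approx(560.0, rel=0.01)
    assert samples.std() / samples.mean() == pytest.approx(0.2, rel=0.05)
    with pytest.raises(ValueError):
        gamma_from_moments(-1.0, 0.2)
    with pytest.raises(ValueError):
        gamma_from_moments(560.0, 0.0)


def test_beta_from_moments_mean_and_sd():
    bp = beta_from_moments(0.3, 0.06)
    nu = bp.alpha + bp.beta
    assert bp.mean == pytest.approx(0.3)
    var = bp.alpha * bp.beta / (nu**2 * (nu + 1))
    assert np.sqrt(var) == pytest.approx(0.06, rel=1e-9)


def test_psa_is_deterministic_given_seed(params):
    cfg = PSAConfig(n_iterations=200, seed=11)
    a, b = run_psa(params, cfg), run_psa(params, cfg)
    for k in ("euglycemia", "gdm", "delta"):
        assert np.array_equal(a.draws[k], b.draws[k])
    c = run_psa(params, PSAConfig(n_iterations=200, seed=12))
    assert not np.array_equal(a.draws["gdm"], c.draws["gdm"])


def test_psa_summaries_are_ordered(params):
    res = run_psa(params, PSAConfig(n_iterations=2000, seed=5))
    for k, s in res.summaries.items():
        assert len(res.draws[k]) == 2000
        assert s["min"] <= s["p10"] <= s["mean"] <= s["p90"] <= s["max"]


@pytest.mark.parametrize("source, infant_sampling", [("counts", "dirichlet"), ("moments", "independent")])
def test_psa_mean_recovers_base_case(params, source, infant_sampling):
    """Moment-matched distributions keep the expectation at the base case,
    whichever sampling scheme is configured."""
    cfg = PSAConfig(
        n_iterations=10_000,
        seed=2,
        probability_source=source,
        infant_sampling=infant_sampling,
    )
    res = run_psa(params, cfg)
    for g in ("euglycemia", "gdm"):
        assert res.summaries[g]["mean"] == pytest.approx(
            _base_inpatient(params, g), rel=0.01
        )
    np.testing.assert_allclose(
        res.draws["delta"], res.draws["gdm"] - res.draws["euglycemia"]
    )


def test_psa_config_validation():
    with pytest.raises(ValueError):
        PSAConfig(n_iterations=0)
    with pytest.raises(ValueError):
        PSAConfig(cost_cv=-0.1)
    with pytest.raises(ValueError):
        PSAConfig(probability_source="guesswork")
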