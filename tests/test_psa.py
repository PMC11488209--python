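"""Monte Carlo sensitivity analysis: calibration, sampling, summaries, scenarios."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from econsult_cba.calibration import reference_case_spec
from econsult_cba.errors import DomainError
from econsult_cba.psa import (
    DistributionSpec,
    PsaSpec,
    aggregate_model,
    beta_from_moments,
    gamma_from_moments,
    one_way_scenario,
    percentile_ci,
    run_psa,
    sd_from_ci95,
    with_seed,
)


def test_gamma_moments_round_trip():
    shape, scale = gamma_from_moments(389_439, 30_563.52)
    assert shape * scale == pytest.approx(389_439)  # mean
    assert shape * scale**2 == pytest.approx(30_563.52**2)  # variance
    # independent check through scipy's parameterization
    dist = scipy.stats.gamma(shape, scale=scale)
    assert dist.mean() == pytest.approx(389_439)
    assert dist.std() == pytest.approx(30_563.52)


def test_gamma_exponential_special_case():
    shape, _ = gamma_from_moments(5.0, 5.0)
    assert shape == pytest.approx(1.0)


def test_beta_moments_round_trip():
    a, b = beta_from_moments(0.84, 0.0149)
    dist = scipy.stats.beta(a, b)
    assert dist.mean() == pytest.approx(0.84)
    assert dist.std() == pytest.approx(0.0149)


def test_beta_uniform_special_case():
    a, b = beta_from_moments(0.5, np.sqrt(1 / 12))
    assert a == pytest.approx(1.0) and b == pytest.approx(1.0)


def test_moment_calibration_domain_errors():
    with pytest.raises(DomainError):
        gamma_from_moments(-1, 1)
    with pytest.raises(DomainError):
        beta_from_moments(0.5, 0.6)  # sd^2 >= mean(1-mean)
    with pytest.raises(DomainError):
        sd_from_ci95(10, 5)


@pytest.mark.parametrize(
    "lo, hi, sd",
    [
        (100_014, 203_922, 26_507.142857),
        (331_417, 451_226, 30_563.520408),
        (7.0, 7.0, 0.0),
    ],
)
def test_sd_from_ci95_hand_arithmetic(lo, hi, sd):
    assert sd_from_ci95(lo, hi) == pytest.approx(sd)


@pytest.mark.parametrize(
    "spec",
    [
        DistributionSpec("gamma", 145_020.0, 26_507.1),
        DistributionSpec("beta", 0.84, 0.0149),
    ],
)
def test_sampled_moments_recover_spec(spec):
    """Empirical mean/SD of 1e5 draws match the calibration within 4 MC SEs."""
    rng = np.random.default_rng(42)
    n = 100_000
    x = spec.sample(rng, n)
    se_mean = spec.sd / np.sqrt(n)
    assert abs(x.mean() - spec.mean) < 4 * se_mean
    # SE of the sample SD ~ sd / sqrt(2n) for light-tailed distributions
    assert abs(x.std(ddof=1) - spec.sd) < 6 * spec.sd / np.sqrt(2 * n)


def test_percentile_ci_order_statistic_oracle():
    draws = np.arange(1, 1001, dtype=float)
    lo, hi = percentile_ci(draws)
    assert (lo, hi) == (pytest.approx(25.975), pytest.approx(975.025))
    c = np.full(10, 3.25)
    assert percentile_ci(c) == (3.25, 3.25)
    rng = np.random.default_rng(0)
    shuffled = rng.permutation(draws)
    assert percentile_ci(shuffled) == (lo, hi)


def test_run_psa_point_specs_degenerate():
    spec = PsaSpec(
        {
            "total_benefit": DistributionSpec("point", 389_439.0),
            "total_cost": DistributionSpec("point", 145_020.0),
        },
        n_draws=50,
        seed=1,
    )
    out = run_psa(aggregate_model, spec)
    assert out.draws["roi"].nunique() == 1
    assert out.means["roi"] == pytest.approx(389_439 / 145_020 - 1)
    assert out.ci_low["roi"] == out.ci_high["roi"]


def test_run_psa_per_draw_identity_and_jensen():
    out = run_psa(aggregate_model, reference_case_spec(seed=5))
    assert np.allclose(out.draws["bcr"] - out.draws["roi"], 1.0)
    assert out.means["bcr"] - out.means["roi"] == pytest.approx(1.0)
    # Jensen: mean of per-draw ratios exceeds ratio of means when cost varies
    ratio_of_means = out.means["total_benefit"] / out.means["total_cost"]
    assert out.means["bcr"] > ratio_of_means
    # linearity: net-benefit mean equals mean difference exactly
    assert out.means["net_benefit"] == pytest.approx(
        out.means["total_benefit"] - out.means["total_cost"]
    )


def test_seed_determinism_and_cross_seed_stability():
    a = run_psa(aggregate_model, reference_case_spec(seed=11))
    b = run_psa(aggregate_model, reference_case_spec(seed=11))
    assert a.draws.equals(b.draws)
    c = run_psa(aggregate_model, reference_case_spec(seed=12))
    se = a.draws["roi"].std(ddof=1) / np.sqrt(len(a.draws))
    assert abs(a.means["roi"] - c.means["roi"]) < 3 * (se * np.sqrt(2))


def test_substreams_stable_under_added_quantity():
    spec = reference_case_spec(seed=3)
    widened = PsaSpec(
        {**spec.quantity_specs, "extra": DistributionSpec("point", 1.0)},
        n_draws=spec.n_draws,
        seed=3,
    )
    a = run_psa(aggregate_model, spec)
    b = run_psa(aggregate_model, widened)
    assert a.draws.equals(b.draws)


def test_one_way_scenario_identity_and_doubling():
    spec = reference_case_spec(seed=9)
    base = run_psa(aggregate_model, spec)
    same = one_way_scenario(aggregate_model, spec, cost_multiplier=1.0)
    assert base.draws.equals(same.draws)
    doubled = one_way_scenario(aggregate_model, spec, cost_multiplier=2.0)
    assert np.allclose(doubled.draws["total_cost"], 2 * base.draws["total_cost"])
    assert np.allclose(doubled.draws["total_benefit"], base.draws["total_benefit"])


def test_one_way_doubling_point_hand_arithmetic():
    spec = PsaSpec(
        {
            "total_benefit": DistributionSpec("point", 389_439.0),
            "total_cost": DistributionSpec("point", 145_020.0),
        },
        n_draws=10,
        seed=0,
    )
    out = one_way_scenario(aggregate_model, spec, cost_multiplier=2.0)
    assert out.means["roi"] == pytest.approx((389_439 - 2 * 145_020) / (2 * 145_020))
    assert round(out.means["roi"], 3) == 0.343


def test_distribution_spec_validation():
    with pytest.raises(DomainError):
        DistributionSpec("gamma", -1.0, 1.0)
    with pytest.raises(DomainError):
        DistributionSpec("beta", 1.2, 0.1)
    with pytest.raises(DomainError):
        DistributionSpec("point", 1.0, 0.5)
    with pytest.raises(DomainError):
        DistributionSpec("lognormal", 1.0, 0.5)
    with pytest.raises(DomainError):
        PsaSpec({}, n_draws=0)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_with_seed_round_trips(seed):
    spec = with_seed(reference_case_spec(seed=0), seed)
    assert spec.seed == seed and spec.n_draws == 1000
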