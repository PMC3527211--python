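"""ABC age estimation: calibration arithmetic, acceptance behaviour, and the
fitted-model interface."""
import numpy as np
import pandas as pd
import pytest

from invgen import (
    ABCConfig,
    InversionAgeModel,
    abc_rejection,
    ages_from_posterior,
    divergence_age,
    expected_theta,
    posterior_summary,
)
from invgen.abc import AcceptanceBudgetError


def test_expected_theta_hand_value():
    assert expected_theta(L=5000, d=0.06, t_gen=3e7, Ne=1e6, f=0.2) == pytest.approx(4.0)
    # linear in f
    assert expected_theta(5000, 0.06, 3e7, 1e6, 0.4) == pytest.approx(8.0)
    with pytest.raises(ValueError):
        expected_theta(5000, 0.0, 3e7, 1e6, 0.2)


def test_config_derives_prior_bound():
    cfg = ABCConfig(L=5000, d=0.06, f=0.2)
    assert cfg.theta_hat == pytest.approx(4.0)
    assert cfg.theta_prior_max == pytest.approx(40.0)
    assert cfg.mu_region_per_year == pytest.approx(5e-5)


def test_age_conversion_hand_value():
    cfg = ABCConfig(L=5000, d=0.06, f=0.2)  # mu_region/year = 5e-5
    draws = pd.DataFrame(dict(alpha=[1.0, 1.0], theta=[4.0, 4.0], t_mrca=[0.5, 0.0]))
    ages = ages_from_posterior(draws, cfg)
    assert ages[0] == pytest.approx(40_000.0)
    assert ages[1] == 0.0
    # ages scale inversely with generations per year
    cfg2 = ABCConfig(L=5000, d=0.06, f=0.2, gens_per_year=20.0)
    assert ages_from_posterior(draws, cfg2)[0] == pytest.approx(20_000.0)


def test_posterior_summary_quantile_convention():
    med, lo, hi = posterior_summary(np.arange(1.0, 101.0))
    assert (med, lo, hi) == pytest.approx((50.5, 3.475, 97.525))
    assert posterior_summary([7.0, 7.0, 7.0]) == (7.0, 7.0, 7.0)
    shuffled = np.random.default_rng(0).permutation(np.arange(1.0, 101.0))
    assert posterior_summary(shuffled) == pytest.approx((50.5, 3.475, 97.525))
    with pytest.raises(ValueError):
        posterior_summary([])


def test_divergence_age_cases():
    years, recent = divergence_age(1e-3, 0.0, 1e-9)
    assert years == pytest.approx(5e5) and not recent
    years, recent = divergence_age(0.004, 0.004, 1e-9)
    assert years == 0.0 and recent
    years, recent = divergence_age(0.003, 0.004, 1e-9)
    assert years < 0 and recent
    with pytest.raises(ValueError):
        divergence_age(1e-3, 0.0, 0.0)


@pytest.fixture(scope="module")
def small_config():
    return ABCConfig(L=5000, d=0.06, f=0.2, min_accept=150, seed=42)


def test_rejection_is_deterministic(small_config):
    a = abc_rejection(6, 2.0, 6, small_config)
    b = abc_rejection(6, 2.0, 6, small_config)
    assert a.draws.equals(b.draws)
    assert a.acceptance_rate == b.acceptance_rate
    assert len(a) >= small_config.min_accept


def test_zero_observation_conditions_on_empty_trees(small_config):
    """obs S = 0 accepts only mutation-free simulations, which pulls T_MRCA
    far below its prior mean (the configuration of an inversion with no
    segregating sites)."""
    post = abc_rejection(0, 0.0, 8, small_config)
    # every accepted draw simulated S = 0, hence a strictly positive age is
    # still possible but trees must be short relative to the prior
    from invgen.coalescent import batch_s_pi

    rng = np.random.default_rng(1)
    thetas = rng.uniform(0, small_config.theta_prior_max, 4000)
    alphas = rng.uniform(0, small_config.alpha_prior_max, 4000)
    _, _, prior_t = batch_s_pi(8, thetas, alphas, rng)
    assert np.median(post.draws["t_mrca"]) < np.median(prior_t)


def test_acceptance_rate_decreases_with_tolerance():
    rates = []
    for tol in (0.10, 0.05, 0.02):
        cfg = ABCConfig(
            L=5000, d=0.06, f=0.2, min_accept=120, seed=5, tolerance=tol
        )
        rates.append(abc_rejection(12, 4.0, 8, cfg).acceptance_rate)
    assert rates[0] > rates[1] >= rates[2]


def test_posterior_age_increases_with_observed_sites():
    medians = []
    for obs_s, obs_pi in ((0, 0.0), (8, 3.0), (30, 11.0)):
        cfg = ABCConfig(L=20_000, d=0.06, f=0.2, min_accept=150, seed=3)
        post = abc_rejection(obs_s, obs_pi, 8, cfg)
        medians.append(np.median(post.ages_years))
    assert medians[0] < medians[1] < medians[2]


def test_budget_exhaustion_raises_with_partial_draws():
    cfg = ABCConfig(
        L=5000, d=0.06, f=0.2, min_accept=1_000, seed=1, max_attempts=2_000
    )
    with pytest.raises(AcceptanceBudgetError) as err:
        abc_rejection(500, 200.0, 8, cfg)  # wildly incompatible observation
    assert err.value.acceptance_rate <= 1.0


def test_model_results_interface(small_config):
    model = InversionAgeModel(obs_s=6, obs_pi=2.0, n=6, config=small_config)
    res = model.fit()
    med, lo, hi = res.age_summary()
    assert lo <= med <= hi
    assert 0 < res.acceptance_rate <= 1
    text = res.summary()
    assert "acceptance rate" in text and "age median" in text
    table = res.param_summary()
    assert set(table["parameter"]) == {"theta", "alpha", "t_mrca", "age_years"}


def test_model_from_alignment():
    from invgen import from_sequences
    from conftest import meta_frame

    seqs = ["AAAA", "AAAT", "AATA", "CCCC", "CCCC"]
    ids = list("abcde")
    meta = meta_frame(ids, ["inverted"] * 3 + ["standard"] * 2)
    aln = from_sequences(ids, seqs, meta=meta)
    cfg = ABCConfig(L=4, d=0.06, f=0.2, min_accept=10, seed=0)
    model = InversionAgeModel.from_alignment(aln, "InX", cfg)
    assert model.n == 3 and model.obs_s == 2
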