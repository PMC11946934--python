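"""Link function, likelihood, gradient, sampler and hierarchy behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from matcod import hmc
from matcod.causes import CAUSES
from matcod.io import Dataset, Observation
from matcod.model import (
    ModelConfig,
    _build_logp_grad,
    _dataset_arrays,
    alr,
    diagnostics,
    fit,
    log_likelihood,
    region_predictive_draws,
    softmax_complete,
)
from matcod.simulate import SimConfig, generate


# --------------------------------------------------------------------------
# softmax_complete / alr


def test_softmax_complete_uniform_at_zero():
    p = softmax_complete(np.zeros(6))
    assert np.allclose(p, 1 / 7)


def test_softmax_complete_closed_form_k2():
    p = softmax_complete(np.array([math.log(2)]), reference_cause="b", causes=("a", "b"))
    assert np.allclose(p, [2 / 3, 1 / 3])


def test_softmax_complete_rejects_non_finite():
    with pytest.raises(ValueError, match="finite"):
        softmax_complete(np.array([np.nan] * 6))


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-20, 20), min_size=6, max_size=6),
    st.sampled_from(CAUSES),
)
def test_softmax_complete_simplex_and_alr_round_trip(v, ref):
    v = np.asarray(v)
    p = softmax_complete(v, reference_cause=ref)
    assert p.shape == (7,)
    assert abs(p.sum() - 1) < 1e-12
    assert (p > 0).all()
    assert np.allclose(alr(p, reference_cause=ref), v, atol=1e-9)


# --------------------------------------------------------------------------
# observation log-likelihood


def test_log_likelihood_closed_form_k2():
    obs = Observation("AAA", "R1", 2010, 2010, "crvs", np.array([3, 1]), 4)
    # p = (0.5, 0.5): C(4,3) * 0.5^4 = 0.25
    ll = log_likelihood(np.zeros(1), obs, reference_cause="b", causes=("a", "b"))
    assert np.isclose(ll, math.log(0.25))


def test_log_likelihood_maximal_when_concentrated():
    counts = np.zeros(7, dtype=np.int64)
    counts[2] = 50
    obs = Observation("AAA", "R1", 2010, 2010, "crvs", counts, 50)
    v = np.zeros(6)
    v[2] = 30.0  # p essentially a point mass on cause 3
    ll = log_likelihood(v, obs)
    assert np.isclose(ll, 0.0, atol=1e-8)  # only the multinomial coefficient, log(1)


def test_log_likelihood_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(50):
        counts = rng.integers(0, 6, size=7)
        if counts.sum() == 0:
            counts[0] = 1
        obs = Observation("AAA", "R1", 2010, 2010, "crvs", counts, int(counts.sum()))
        v = rng.normal(0, 1.5, size=6)
        p = softmax_complete(v)
        n = int(counts.sum())
        brute = math.factorial(n)
        for c in counts:
            brute /= math.factorial(int(c))
        brute = math.log(brute) + sum(
            int(c) * math.log(pk) for c, pk in zip(counts, p)
        )
        assert np.isclose(log_likelihood(v, obs), brute, atol=1e-9)


def test_log_likelihood_skips_empty_observation_with_warning():
    obs = Observation("AAA", "R1", 2010, 2010, "crvs", np.zeros(7, dtype=np.int64), 5)
    with pytest.warns(UserWarning, match="no assigned causes"):
        assert log_likelihood(np.zeros(6), obs) == 0.0


# --------------------------------------------------------------------------
# posterior log-density gradient


def test_posterior_gradient_matches_finite_differences():
    ds, _ = generate(SimConfig(n_regions=2, countries_per_region=2, seed=3))
    countries, regions, roc, counts, n_total, cidx, sidx = _dataset_arrays(ds)
    lg, lay = _build_logp_grad(
        counts, n_total, cidx, sidx, roc, len(regions), 5, ModelConfig()
    )
    rng = np.random.default_rng(0)
    theta = 0.3 * rng.standard_normal(lay.dim)
    _, g = lg(theta)
    eps = 1e-6
    for i in rng.choice(lay.dim, 30, replace=False):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (lg(tp)[0] - lg(tm)[0]) / (2 * eps)
        assert abs(fd - g[i]) < 1e-4 * max(1.0, abs(fd))


# --------------------------------------------------------------------------
# sampler correctness: 1-D quadrature oracle


def test_hmc_matches_quadrature_on_binomial_logit_posterior():
    # one K=2 observation, fixed prior on the log-odds (no hierarchy)
    m0, s0, counts, n = 0.3, 0.8, 27, 60
    grid = np.linspace(-8, 8, 20001)
    logpost = counts * grid - n * np.log1p(np.exp(grid)) - 0.5 * ((grid - m0) / s0) ** 2
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    p_grid = 1 / (1 + np.exp(-grid))
    q_mean = float((w * p_grid).sum())
    q_sd = float(np.sqrt((w * p_grid**2).sum() - q_mean**2))

    def lg(th):
        v = float(th[0])
        pv = 1 / (1 + np.exp(-v)) if v > -30 else np.exp(v)
        log1pexp = max(v, 0.0) + np.log1p(np.exp(-abs(v)))
        lp = counts * v - n * log1pexp - 0.5 * ((v - m0) / s0) ** 2
        return lp, np.array([counts - n * pv - (v - m0) / s0**2])

    x0s = [np.array([x]) for x in (0.1, -0.1, 0.5, 0.0)]
    draws, _ = hmc.sample(lg, x0s, 300, 500, seed=3, leapfrog_steps=8)
    p_draws = 1 / (1 + np.exp(-draws.reshape(-1)))
    assert abs(p_draws.mean() - q_mean) < 0.01
    assert abs(p_draws.std() - q_sd) < 0.01


# --------------------------------------------------------------------------
# full fits


def test_posterior_draw_invariants_and_convergence(small_fit):
    small_fit.validate_draws()
    assert small_fit.diagnostics["rhat_max"] < 1.05
    assert small_fit.diagnostics["n_divergent"] <= 0.005 * small_fit.n_total_draws


def test_large_n_posterior_matches_empirical_proportions(obs_factory, env_factory):
    # one country, one huge observation, vague hierarchy
    counts = np.array([8000, 7000, 27000, 16000, 7000, 10000, 25000])
    obs = obs_factory("AAA", counts, n_total=int(counts.sum()))
    ds = Dataset([obs], env_factory(["AAA"]), {"AAA": "R1"})
    ps = fit(ds, ModelConfig(chains=2, warmup=400, draws=400, seed=11, min_ess=50))
    med = np.median(ps.p_draws("AAA"), axis=0)
    emp = counts / counts.sum()
    assert np.abs(med - emp).max() < 0.01


def test_no_data_country_follows_region_predictive(small_sim, small_fit):
    ds, _ = small_sim
    with_data = {o.country for o in ds.observations}
    empty = [c for c in ds.countries if c not in with_data]
    assert empty, "fixture should include a country without observations"
    c = empty[0]
    pred = region_predictive_draws(small_fit, ds.region_map[c], seed=123)
    own = small_fit.p_draws(c)
    for k in range(len(CAUSES)):
        assert ks_2samp(own[:, k], pred[:, k]).statistic < 0.1


def test_source_weighting_monotone(source_weighting_kls):
    # the same extra data moves the posterior more when filed as most-trusted
    assert (
        source_weighting_kls["confidential_enquiry"]
        > source_weighting_kls["subnational_study"]
    )


def test_partial_assignment_inflation_widens_intervals(partial_assignment_widths):
    full = partial_assignment_widths["full"]
    quarter = partial_assignment_widths["quarter"]
    assert quarter.mean() > full.mean()
    assert (quarter > 0.95 * full).all()  # no cause interval may shrink materially


def test_reference_category_choice_does_not_move_estimates(two_country_dataset):
    meds = {}
    for ref in ("other_direct", "abortion"):
        cfg = ModelConfig(
            chains=2, warmup=400, draws=400, seed=5, min_ess=100, reference_cause=ref
        )
        ps = fit(two_country_dataset, cfg)
        meds[ref] = np.median(ps.p_flat(), axis=0)
    assert np.abs(meds["other_direct"] - meds["abortion"]).max() < 0.05


# --------------------------------------------------------------------------
# diagnostics


def _fake_ps(chain_values):
    """Posterior container filled with externally supplied eta chains."""
    from matcod.model import PosteriorSamples

    eta = np.asarray(chain_values)  # (chains, draws, 1, 1)
    ch, dr = eta.shape[:2]
    return PosteriorSamples(
        causes=("a", "b"),
        reference_cause="b",
        countries=["AAA"],
        regions=["R1"],
        country_region_idx=np.array([0]),
        mu0=eta[:, :, 0, :],
        tau=np.abs(eta[:, :, 0, 0]) + 0.5,
        mu_region=eta,
        eta=eta,
        p=np.stack([1 / (1 + np.exp(-eta[..., 0])), 1 - 1 / (1 + np.exp(-eta[..., 0]))], axis=-1),
        chol=np.ones((ch, dr, 1, 1)),
        sigma_source=np.tile(np.array([0.1, 0.2, 0.3, 0.4]), (ch, dr, 1)),
    )


def test_rhat_one_for_identical_chains():
    rng = np.random.default_rng(0)
    chain = rng.standard_normal((1, 400, 1, 1))
    ps = _fake_ps(np.concatenate([chain, chain], axis=0))
    rep = diagnostics(ps, min_ess=1.0)
    assert rep["rhat_max"] < 1.01


def test_rhat_flags_chains_at_different_fixed_points():
    rng = np.random.default_rng(0)
    a = 0.01 * rng.standard_normal((1, 400, 1, 1))
    b = 5.0 + 0.01 * rng.standard_normal((1, 400, 1, 1))
    ps = _fake_ps(np.concatenate([a, b], axis=0))
    rep = diagnostics(ps, min_ess=1.0)
    assert rep["rhat_max"] > 1.1
    assert not rep["converged"]


def test_diagnostics_require_two_chains():
    rng = np.random.default_rng(0)
    ps = _fake_ps(rng.standard_normal((1, 400, 1, 1)))
    with pytest.raises(ValueError, match="2 chains"):
        diagnostics(ps)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(chains=1).validate()
    with pytest.raises(ValueError):
        ModelConfig(partial_assignment="bogus").validate()
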