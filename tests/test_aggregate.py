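"""HIV incorporation, envelope-weighted aggregation and subgroup splits."""

import numpy as np
import pytest

from matcod.aggregate import (
    RegionalSummary,
    SubgroupSplit,
    aggregate,
    fit_subgroup_model,
    incorporate_hiv,
    split_subgroups,
)
from matcod.causes import CAUSES
from matcod.io import Dataset
from matcod.model import ModelConfig, PosteriorSamples
from tests.conftest import make_envelope, make_obs


def _manual_ps(p_draws, countries, regions, region_idx):
    """Wrap externally constructed composition draws (S, C, K) in a posterior."""
    S, C, K = p_draws.shape
    d = K - 1
    return PosteriorSamples(
        causes=CAUSES,
        reference_cause="other_direct",
        countries=list(countries),
        regions=list(regions),
        country_region_idx=np.asarray(region_idx),
        mu0=np.zeros((1, S, d)),
        tau=np.ones((1, S)),
        mu_region=np.zeros((1, S, len(regions), d)),
        eta=np.zeros((1, S, C, d)),
        p=p_draws[None, ...],
        chol=np.tile(np.eye(d), (1, S, 1, 1)),
        sigma_source=np.tile(np.array([0.1, 0.2, 0.3, 0.4]), (1, S, 1)),
    )


def _dirichlet_draws(S, C, rng):
    return rng.dirichlet(np.full(len(CAUSES), 2.0), size=(S, C))


# --------------------------------------------------------------------------
# HIV incorporation


def test_hiv_zero_is_identity():
    rng = np.random.default_rng(0)
    p = _dirichlet_draws(50, 1, rng)
    assert np.allclose(incorporate_hiv(p, 0.0), p)


def test_hiv_one_is_all_indirect():
    rng = np.random.default_rng(0)
    p = _dirichlet_draws(50, 1, rng)
    out = incorporate_hiv(p, 1.0)
    ind = CAUSES.index("indirect")
    assert np.allclose(out[..., ind], 1.0)
    assert np.allclose(np.delete(out, ind, axis=-1), 0.0)


def test_hiv_uniform_arithmetic_case():
    p = np.full((1, 7), 1 / 7)
    out = incorporate_hiv(p, 0.3)
    ind = CAUSES.index("indirect")
    expected = np.full(7, 0.1)
    expected[ind] = 0.4
    assert np.allclose(out[0], expected)


def test_hiv_preserves_simplex_and_is_monotone_in_h():
    rng = np.random.default_rng(1)
    p = _dirichlet_draws(20, 3, rng)
    ind = CAUSES.index("indirect")
    prev = None
    for h in np.linspace(0, 1, 6):
        out = incorporate_hiv(p, h)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-12)
        if prev is not None:
            assert (out[..., ind] >= prev - 1e-12).all()
        prev = out[..., ind]
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        incorporate_hiv(p, 1.2)


# --------------------------------------------------------------------------
# aggregation


def test_identical_countries_make_region_equal_country():
    rng = np.random.default_rng(2)
    p1 = _dirichlet_draws(100, 1, rng)
    p = np.concatenate([p1, p1], axis=1)  # two countries, identical draws
    ps = _manual_ps(p, ["AAA", "BBB"], ["R1"], [0, 0])
    env = make_envelope(["AAA", "BBB"], deaths=500.0)
    agg = aggregate(ps, env, with_hiv=False)
    reg = agg.summary_for("region", "R1")
    cty = agg.summary_for("country", "AAA")
    assert np.allclose(reg.prop_median, cty.prop_median)
    assert np.allclose(reg.deaths_median, 2 * cty.deaths_median)


def test_degenerate_composition_routes_all_deaths_to_one_cause():
    p = np.zeros((10, 1, 7))
    p[..., 0] = 1.0
    ps = _manual_ps(p, ["AAA"], ["R1"], [0])
    env = make_envelope(["AAA"], deaths=1000.0 / 12)  # 1000 over the window
    agg = aggregate(ps, env, with_hiv=False)
    s = agg.summary_for("country", "AAA")
    assert np.isclose(s.deaths_median[0], 1000.0)
    assert np.allclose(s.deaths_median[1:], 0.0)


def test_per_draw_conservation_at_every_level(small_sim, small_fit):
    ds, _ = small_sim
    agg = aggregate(small_fit, ds.envelope, window=ds.window)
    env_c = agg.env_country
    assert np.allclose(
        agg.country_deaths.sum(axis=2), env_c[None, :], rtol=1e-9, atol=0
    )
    assert np.allclose(
        agg.region_deaths.sum(axis=2), agg.env_region[None, :], rtol=1e-9, atol=0
    )
    assert np.allclose(
        agg.global_deaths.sum(axis=1), env_c.sum(), rtol=1e-9, atol=0
    )


def test_missing_envelope_country_is_named():
    rng = np.random.default_rng(3)
    ps = _manual_ps(_dirichlet_draws(10, 2, rng), ["AAA", "ZZZ"], ["R1"], [0, 0])
    env = make_envelope(["AAA"])
    with pytest.raises(ValueError, match="ZZZ"):
        aggregate(ps, env)


def test_doubling_envelope_pulls_region_toward_country():
    rng = np.random.default_rng(4)
    pa = rng.dirichlet([8, 1, 1, 1, 1, 1, 1], size=(200, 1))
    pb = rng.dirichlet([1, 1, 8, 1, 1, 1, 1], size=(200, 1))
    p = np.concatenate([pa, pb], axis=1)

    def regional_kl_to_a(deaths_a):
        ps = _manual_ps(p, ["AAA", "BBB"], ["R1"], [0, 0])
        env = make_envelope(["AAA"], deaths=deaths_a)
        env.table = (
            __import__("pandas")
            .concat([env.table, make_envelope(["BBB"], deaths=500.0).table])
            .reset_index(drop=True)
        )
        agg = aggregate(PosteriorSamples(**{**ps.__dict__}), env, with_hiv=False)
        reg = agg.summary_for("region", "R1").prop_median
        a = agg.summary_for("country", "AAA").prop_median
        return float(np.sum(a * np.log(a / reg)))

    assert regional_kl_to_a(1000.0) < regional_kl_to_a(500.0)


def test_summaries_equivariant_under_cause_relabelling():
    rng = np.random.default_rng(5)
    p = _dirichlet_draws(200, 1, rng)
    perm = np.array([3, 0, 6, 1, 5, 2, 4])
    env = make_envelope(["AAA"])
    s1 = aggregate(
        _manual_ps(p, ["AAA"], ["R1"], [0]), env, with_hiv=False
    ).summary_for("country", "AAA")
    ps2 = _manual_ps(p[:, :, perm], ["AAA"], ["R1"], [0])
    ps2.causes = tuple(np.array(CAUSES)[perm])
    s2 = aggregate(ps2, env, with_hiv=False).summary_for("country", "AAA")
    assert np.allclose(s2.prop_median, s1.prop_median[perm])
    assert np.allclose(s2.prop_q10, s1.prop_q10[perm])


def test_quantile_ordering_enforced():
    with pytest.raises(AssertionError, match="quantile ordering"):
        RegionalSummary(
            level="country",
            unit="AAA",
            causes=CAUSES,
            prop_median=np.full(7, 0.1),
            prop_q10=np.full(7, 0.2),  # q10 > median
            prop_q90=np.full(7, 0.3),
            deaths_median=np.ones(7),
            deaths_q10=np.zeros(7),
            deaths_q90=np.full(7, 2.0),
            envelope_deaths=10.0,
        )


# --------------------------------------------------------------------------
# subgroup splits


def _split_from_draws(parent, labels, countries, frac_draws):
    return SubgroupSplit(
        parent=parent, labels=labels, countries=list(countries), draws=frac_draws[None]
    )


def test_point_mass_split_reproduces_parent():
    rng = np.random.default_rng(6)
    p = _dirichlet_draws(100, 1, rng)
    ps = _manual_ps(p, ["AAA"], ["R1"], [0])
    env = make_envelope(["AAA"])
    agg = aggregate(ps, env, with_hiv=False)
    frac = np.zeros((100, 1, 3))
    frac[..., 0] = 1.0
    subs = split_subgroups(
        agg,
        _split_from_draws("haemorrhage", ("antepartum", "intrapartum", "postpartum"), ["AAA"], frac),
    )
    parent = agg.summary_for("global", "global")
    k = CAUSES.index("haemorrhage")
    ap = [s for s in subs if s.subgroup == "antepartum" and s.level == "global"][0]
    assert np.isclose(ap.deaths_median, parent.deaths_median[k])
    others = [s for s in subs if s.subgroup != "antepartum" and s.level == "global"]
    assert all(np.isclose(s.deaths_median, 0.0) for s in others)


def test_subgroup_additivity_per_draw_but_not_in_medians():
    rng = np.random.default_rng(7)
    S = 999
    p = _dirichlet_draws(S, 1, rng)
    ps = _manual_ps(p, ["AAA"], ["R1"], [0])
    agg = aggregate(ps, make_envelope(["AAA"]), with_hiv=False)
    # heavily skewed, right-tailed split draws: medians will not add
    frac = rng.dirichlet([0.2, 0.2, 0.2], size=(S, 1))
    k = CAUSES.index("haemorrhage")
    d_parent = agg.country_deaths[:, 0, k]
    d_subs = d_parent[:, None] * frac[:, 0, :]
    # per-draw conservation is exact
    assert np.allclose(d_subs.sum(axis=1), d_parent, rtol=1e-12)
    subs = split_subgroups(
        agg,
        _split_from_draws("haemorrhage", ("antepartum", "intrapartum", "postpartum"), ["AAA"], frac),
    )
    med_sum = sum(s.deaths_median for s in subs if s.level == "global")
    med_parent = float(np.median(d_parent))
    assert not np.isclose(med_sum, med_parent, rtol=1e-3)


def test_misaligned_split_draws_rejected():
    rng = np.random.default_rng(8)
    p = _dirichlet_draws(50, 1, rng)
    agg = aggregate(_manual_ps(p, ["AAA"], ["R1"], [0]), make_envelope(["AAA"]), with_hiv=False)
    frac = rng.dirichlet([1, 1, 1], size=(40, 1))  # wrong draw count
    with pytest.raises(ValueError, match="not aligned"):
        split_subgroups(
            agg,
            _split_from_draws("haemorrhage", ("antepartum", "intrapartum", "postpartum"), ["AAA"], frac),
        )


@pytest.fixture(scope="module")
def subgroup_cfg():
    return ModelConfig(chains=2, warmup=400, draws=400, seed=5, min_ess=50)


def test_subgroup_fit_recovers_concentrated_timing(subgroup_cfg):
    observations = [
        make_obs("AAA", [20, 15, 60, 35, 15, 25, 30], sub={"haemorrhage": np.array([0, 0, 60])}),
        make_obs("BBB", [30, 10, 50, 40, 10, 30, 30], sub={"haemorrhage": np.array([0, 0, 50])}),
    ]
    ds = Dataset(observations, make_envelope(["AAA", "BBB"]), {"AAA": "R1", "BBB": "R1"})
    split = fit_subgroup_model(ds, "haemorrhage", subgroup_cfg)
    split.validate()
    pp = split.draws_flat()[:, 0, split.labels.index("postpartum")]
    assert np.median(pp) > 0.95


def test_subgroup_fit_symmetric_for_balanced_single_observation(subgroup_cfg):
    observations = [
        make_obs("AAA", [5, 5, 3, 5, 5, 5, 5], sub={"haemorrhage": np.array([1, 1, 1])})
    ]
    ds = Dataset(observations, make_envelope(["AAA", "BBB"]), {"AAA": "R1", "BBB": "R1"})
    split = fit_subgroup_model(ds, "haemorrhage", subgroup_cfg)
    meds = np.median(split.draws_flat()[:, 0, :], axis=0)
    diffs = np.abs(meds[:, None] - meds[None, :])
    assert diffs.max() < 0.05


def test_subgroup_fit_without_data_falls_back_to_prior(subgroup_cfg):
    observations = [make_obs("AAA", [5, 5, 3, 5, 5, 5, 5])]
    ds = Dataset(observations, make_envelope(["AAA"]), {"AAA": "R1"})
    with pytest.warns(UserWarning, match="no subgroup data"):
        split = fit_subgroup_model(ds, "sepsis", subgroup_cfg)
    split.validate()


def test_subgroup_fit_rejects_unknown_parent(subgroup_cfg):
    ds = Dataset(
        [make_obs("AAA", [5, 5, 3, 5, 5, 5, 5])], make_envelope(["AAA"]), {"AAA": "R1"}
    )
    with pytest.raises(ValueError, match="no subgroup scheme"):
        fit_subgroup_model(ds, "embolism", subgroup_cfg)
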