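"""Shared fixtures: small synthetic datasets and (expensive) model fits.

Model fits are session-scoped so several tests can interrogate the same
posterior without re-sampling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from matcod.io import Dataset, EnvelopeTable, Observation
from matcod.model import ModelConfig, fit
from matcod.simulate import SimConfig, generate

warnings.filterwarnings("ignore", category=FutureWarning)


def make_envelope(countries, deaths=1000.0, hiv=0.0, years=(2009, 2020)):
    rows = [
        (c, y, float(deaths), float(hiv))
        for c in countries
        for y in range(years[0], years[1] + 1)
    ]
    return EnvelopeTable(
        pd.DataFrame(rows, columns=["country", "year", "deaths", "hiv_proportion"])
    )


def make_obs(country, counts, source_type="crvs", n_total=None, region="R1", sub=None):
    counts = np.asarray(counts, dtype=np.int64)
    return Observation(
        country=country,
        region=region,
        period_start=2012,
        period_end=2014,
        source_type=source_type,
        counts=counts,
        n_total=int(n_total if n_total is not None else counts.sum()),
        subgroup_counts=sub,
    )


@pytest.fixture(scope="session")
def env_factory():
    return make_envelope


@pytest.fixture(scope="session")
def obs_factory():
    return make_obs


@pytest.fixture(scope="session")
def small_sim():
    """Two regions x three countries, one country left without data."""
    cfg = SimConfig(
        n_regions=2,
        countries_per_region=3,
        obs_per_country=2,
        missing_country_fraction=0.2,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_fit_config():
    return ModelConfig(chains=2, warmup=500, draws=500, seed=7, min_ess=100)


@pytest.fixture(scope="session")
def small_fit(small_sim, small_fit_config):
    ds, _ = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(ds, small_fit_config)


@pytest.fixture(scope="session")
def two_country_dataset():
    """A fixed two-country dataset used by the monotonicity studies."""
    observations = [
        make_obs("AAA", [20, 15, 60, 35, 15, 25, 30]),
        make_obs("BBB", [30, 10, 50, 40, 10, 30, 30]),
    ]
    env = make_envelope(["AAA", "BBB"])
    return Dataset(observations, env, {"AAA": "R1", "BBB": "R1"})


def _eta_moments(ps, country):
    E = ps.eta.reshape(-1, len(ps.countries), len(ps.causes) - 1)
    E = E[:, ps.countries.index(country), :]
    return E.mean(axis=0), np.cov(E.T)


def _gaussian_kl(m0, S0, m1, S1):
    d = len(m0)
    iS1 = np.linalg.inv(S1)
    return 0.5 * (
        np.trace(iS1 @ S0)
        + (m1 - m0) @ iS1 @ (m1 - m0)
        - d
        + float(np.log(np.linalg.det(S1) / np.linalg.det(S0)))
    )


@pytest.fixture(scope="session")
def source_weighting_kls(two_country_dataset):
    """KL shift of one country's posterior when a new observation arrives,
    by the reliability tier the duplicate is filed under."""
    cfg = ModelConfig(chains=2, warmup=400, draws=400, seed=5, min_ess=100)
    extra = [25, 5, 80, 30, 10, 20, 30]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = fit(two_country_dataset, cfg)
        m0, S0 = _eta_moments(base, "AAA")
        kls = {}
        for src in ("confidential_enquiry", "subnational_study"):
            ds = Dataset(
                two_country_dataset.observations + [make_obs("AAA", extra, source_type=src)],
                two_country_dataset.envelope,
                dict(two_country_dataset.region_map),
            )
            ps = fit(ds, cfg)
            m1, S1 = _eta_moments(ps, "AAA")
            kls[src] = _gaussian_kl(m1, S1, m0, S0)
    return kls


@pytest.fixture(scope="session")
def partial_assignment_widths(two_country_dataset):
    """80%-interval widths for one country at full vs quarter cause assignment."""
    cfg = ModelConfig(chains=2, warmup=400, draws=400, seed=5, min_ess=100)
    counts = [20, 15, 60, 35, 15, 25, 30]
    widths = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, mult in (("full", 1), ("quarter", 4)):
            ds = Dataset(
                [
                    make_obs("AAA", counts, n_total=sum(counts) * mult),
                    make_obs("BBB", [30, 10, 50, 40, 10, 30, 30]),
                ],
                two_country_dataset.envelope,
                dict(two_country_dataset.region_map),
            )
            ps = fit(ds, cfg)
            P = ps.p_flat()[:, ps.countries.index("AAA"), :]
            widths[label] = np.quantile(P, 0.9, axis=0) - np.quantile(P, 0.1, axis=0)
    return widths
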