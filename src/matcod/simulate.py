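"""Synthetic maternal cause-of-death datasets with known ground truth.

The generator emulates the statistical structure the estimation model
assumes: countries nested in regions; a per-country non-HIV cause
composition arising from a logistic-normal hierarchy (softmax of a
multivariate normal on additive log-ratios); observations whose counts
are multinomial draws around the country composition perturbed by
source-level noise, with noise SD ordered by source reliability; studies
that assign a cause to only a fraction of their deaths; countries with
no data at all; timing splits for haemorrhage/sepsis; suicide counts in
specialised (non-CRVS) sources only; and late maternal deaths.

Defaults reflect the study conditions: a 2009–20 window, roughly 200
deaths per observation, two observations per country, a haemorrhage-led
global composition, and postpartum-dominant timing splits. When a study
assigns causes to a fraction ``f`` of its deaths, the observation-level
noise SD is inflated by ``sqrt(1/f)`` — the same rule the estimation
model applies — so the default configuration is a well-specified case
for calibration checks.

All randomness derives from one master seed via named substreams, so a
fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .causes import CAUSES, DEFAULT_REFERENCE, SUBGROUPS
from .io import Dataset, EnvelopeTable, Observation, SOURCE_TYPES
import pandas as pd


def _default_global_mean() -> np.ndarray:
    # log-ratios (vs other_direct) of a haemorrhage-led composition:
    # abortion .08, embolism .07, haem .27, hyp .16, sepsis .07,
    # other_direct .10, indirect .25
    p = {
        "abortion": 0.08,
        "embolism": 0.07,
        "haemorrhage": 0.27,
        "hypertension": 0.16,
        "sepsis": 0.07,
        "other_direct": 0.10,
        "indirect": 0.25,
    }
    ref = p[DEFAULT_REFERENCE]
    return np.array(
        [math.log(p[c] / ref) for c in CAUSES if c != DEFAULT_REFERENCE], dtype=float
    )


_DEFAULT_SUBGROUP_DIRICHLET = {
    # postpartum-dominant timing; "other" dominant among other-direct subtypes
    "haemorrhage": (2.0, 1.5, 6.5),
    "sepsis": (2.0, 1.0, 7.0),
    "other_direct": (1.5, 2.0, 2.0, 4.5),
}

_STREAMS = (
    "hyperparameters",
    "envelope",
    "structure",
    "counts",
    "subgroups",
    "suicide_late",
    "missing",
)


@dataclass
class SimConfig:
    n_regions: int = 5
    countries_per_region: int = 5
    years: tuple[int, int] = (2009, 2020)
    global_mean: np.ndarray = field(default_factory=_default_global_mean)
    region_sd: float = 0.3
    country_sd: float = 0.3
    cause_correlation: Optional[np.ndarray] = None  # (K-1, K-1); identity when None
    source_sds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.25)
    source_probs: tuple[float, ...] = (0.1, 0.5, 0.2, 0.2)
    obs_per_country: int = 2
    deaths_per_obs: tuple[int, int] = (150, 250)
    assigned_fraction_range: tuple[float, float] = (0.8, 1.0)
    envelope_deaths_range: tuple[float, float] = (200.0, 5000.0)
    hiv_proportion_range: tuple[float, float] = (0.0, 0.10)
    subgroup_dirichlet: dict = field(
        default_factory=lambda: dict(_DEFAULT_SUBGROUP_DIRICHLET)
    )
    subgroup_report_fraction: float = 0.7
    suicide_country_fraction: float = 0.15
    suicide_rate_range: tuple[float, float] = (0.0, 0.03)
    late_report_fraction: float = 0.6
    late_ratio_range: tuple[float, float] = (0.0, 0.07)
    missing_country_fraction: float = 0.15
    truth_family: str = "logistic_normal"  # or "dirichlet_multinomial"
    dm_concentration: float = 50.0
    seed: int = 0

    @property
    def n_countries(self) -> int:
        return self.n_regions * self.countries_per_region

    def validate(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("need at least one region and one country per region")
        if self.region_sd < 0 or self.country_sd < 0:
            # zero is allowed: a degenerate hierarchy is a useful test case
            raise ValueError("hierarchy SDs must be non-negative")
        sds = np.asarray(self.source_sds, dtype=float)
        if len(sds) != len(SOURCE_TYPES) or (sds <= 0).any():
            raise ValueError("source_sds must be positive, one per source type")
        if (np.diff(sds) < 0).any():
            raise ValueError(
                "source_sds must be non-decreasing in the order "
                + " <= ".join(SOURCE_TYPES)
            )
        if self.cause_correlation is not None:
            R = np.asarray(self.cause_correlation, dtype=float)
            d = len(CAUSES) - 1
            if R.shape != (d, d) or not np.allclose(R, R.T):
                raise ValueError("cause_correlation must be a symmetric (K-1)x(K-1) matrix")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError("cause_correlation must have unit diagonal")
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError("cause_correlation must be positive definite")
        lo, hi = self.assigned_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("assigned_fraction_range must lie in (0, 1]")
        if self.truth_family not in ("logistic_normal", "dirichlet_multinomial"):
            raise ValueError(f"unknown truth_family {self.truth_family!r}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`generate` for recovery/calibration checks."""

    causes: tuple[str, ...]
    countries: list[str]
    regions: list[str]
    country_region: dict[str, str]
    eta_country: np.ndarray  # (C, K-1) additive log-ratios, reference other_direct
    p_country: np.ndarray  # (C, K) simplex rows
    p_region: np.ndarray  # (R, K) envelope-weighted
    p_global: np.ndarray  # (K,)
    mu_global: np.ndarray
    region_effects: np.ndarray
    covariance: np.ndarray
    source_sds: tuple[float, ...]
    subgroup_splits: dict  # parent -> (C, n_sub) simplex rows
    suicide_rate: dict
    late_ratio: dict

    def validate(self) -> None:
        for arr in (self.p_country, self.p_region, self.p_global[None, :]):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise AssertionError("truth proportions must sum to 1")
            if (arr <= 0).any():
                raise AssertionError("truth proportions must be strictly positive")


def _softmax_complete(v: np.ndarray, ref_idx: int) -> np.ndarray:
    # local copy to avoid a circular import with the model module
    v = np.asarray(v, dtype=float)
    full = np.insert(v, ref_idx, 0.0, axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def generate(config: SimConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic dataset and its ground truth. Deterministic under seed."""
    config.validate()
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))
    }
    K = len(CAUSES)
    d = K - 1
    ref_idx = CAUSES.index(DEFAULT_REFERENCE)
    regions = [f"R{r + 1}" for r in range(config.n_regions)]
    countries = [
        f"R{r + 1}C{c + 1:02d}"
        for r in range(config.n_regions)
        for c in range(config.countries_per_region)
    ]
    country_region = {
        cc: regions[i // config.countries_per_region] for i, cc in enumerate(countries)
    }
    C = len(countries)

    # --- hierarchy: truth compositions -------------------------------------
    rng = streams["hyperparameters"]
    R_corr = (
        np.eye(d) if config.cause_correlation is None else np.asarray(config.cause_correlation)
    )
    L_country = config.country_sd * np.linalg.cholesky(R_corr)
    Sigma = L_country @ L_country.T
    region_eff = config.region_sd * rng.standard_normal((config.n_regions, d))
    eta = np.empty((C, d))
    for i, cc in enumerate(countries):
        r = regions.index(country_region[cc])
        eta[i] = config.global_mean + region_eff[r] + L_country @ rng.standard_normal(d)
    p_country = _softmax_complete(eta, ref_idx)

    sub_splits = {
        parent: streams["subgroups"].dirichlet(np.asarray(conc, dtype=float), size=C)
        for parent, conc in config.subgroup_dirichlet.items()
    }

    # --- envelope -----------------------------------------------------------
    rng = streams["envelope"]
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    env_rows = []
    hiv_c = {
        cc: rng.uniform(*config.hiv_proportion_range) for cc in countries
    }
    for cc in countries:
        deaths = rng.uniform(*config.envelope_deaths_range, size=len(years))
        for y, dth in zip(years, deaths):
            env_rows.append((cc, int(y), float(dth), hiv_c[cc]))
    env = EnvelopeTable(
        pd.DataFrame(env_rows, columns=["country", "year", "deaths", "hiv_proportion"])
    )
    ct = env.country_totals(config.years)
    env_w = ct.loc[countries, "deaths"].to_numpy()
    p_region = np.empty((config.n_regions, K))
    for r, rr in enumerate(regions):
        m = np.array([country_region[cc] == rr for cc in countries])
        p_region[r] = (env_w[m, None] * p_country[m]).sum(axis=0) / env_w[m].sum()
    p_global = (env_w[:, None] * p_country).sum(axis=0) / env_w.sum()

    # --- which countries emit data ------------------------------------------
    rng = streams["missing"]
    n_missing = int(round(config.missing_country_fraction * C))
    n_missing = min(n_missing, C - 1)  # at least one country with data
    missing = set(rng.choice(C, size=n_missing, replace=False)) if n_missing else set()

    # --- per-country reporting behaviour ------------------------------------
    rng = streams["suicide_late"]
    reports_suicide = {
        cc: rng.random() < config.suicide_country_fraction for cc in countries
    }
    suicide_rate = {
        cc: rng.uniform(*config.suicide_rate_range) for cc in countries
    }
    reports_late = {cc: rng.random() < config.late_report_fraction for cc in countries}
    late_ratio = {cc: rng.uniform(*config.late_ratio_range) for cc in countries}

    # --- observations --------------------------------------------------------
    s_rng = streams["structure"]
    c_rng = streams["counts"]
    sds = np.asarray(config.source_sds, dtype=float)
    observations: list[Observation] = []
    for i, cc in enumerate(countries):
        if i in missing:
            continue
        for _ in range(config.obs_per_country):
            src = int(s_rng.choice(len(SOURCE_TYPES), p=np.asarray(config.source_probs)))
            lo, hi = config.deaths_per_obs
            n_total = int(s_rng.integers(lo, hi + 1))
            start = int(s_rng.integers(y0, y1 + 1))
            end = min(int(start + s_rng.integers(0, 3)), y1)
            frac = s_rng.uniform(*config.assigned_fraction_range)
            n_assigned = max(1, int(round(frac * n_total)))
            sigma = sds[src] * math.sqrt(n_total / n_assigned)
            if config.truth_family == "logistic_normal":
                delta = sigma * c_rng.standard_normal(d)
                p_obs = _softmax_complete(eta[i] + delta, ref_idx)
            else:
                p_obs = c_rng.dirichlet(p_country[i] * config.dm_concentration)
            counts = c_rng.multinomial(n_assigned, p_obs)

            sub_counts = None
            if s_rng.random() < config.subgroup_report_fraction:
                sub_counts = {}
                for parent, split in sub_splits.items():
                    parent_n = int(counts[CAUSES.index(parent)])
                    sub_counts[parent] = c_rng.multinomial(parent_n, split[i])
            suicide_n = None
            if reports_suicide[cc] and SOURCE_TYPES[src] != "crvs":
                suicide_n = int(c_rng.binomial(n_total, suicide_rate[cc]))
            late_n = None
            if reports_late[cc] and SOURCE_TYPES[src] in ("crvs", "confidential_enquiry"):
                late_n = int(c_rng.poisson(late_ratio[cc] * n_total))
            observations.append(
                Observation(
                    country=cc,
                    region=country_region[cc],
                    period_start=start,
                    period_end=end,
                    source_type=SOURCE_TYPES[src],
                    counts=counts.astype(np.int64),
                    n_total=n_total,
                    subgroup_counts=sub_counts,
                    suicide_count=suicide_n,
                    late_count=late_n,
                )
            )

    ds = Dataset(
        observations=observations,
        envelope=env,
        region_map=dict(country_region),
        window=config.years,
    )
    truth = SyntheticTruth(
        causes=CAUSES,
        countries=countries,
        regions=regions,
        country_region=dict(country_region),
        eta_country=eta,
        p_country=p_country,
        p_region=p_region,
        p_global=p_global,
        mu_global=np.asarray(config.global_mean, dtype=float).copy(),
        region_effects=region_eff,
        covariance=Sigma,
        source_sds=tuple(config.source_sds),
        subgroup_splits=sub_splits,
        suicide_rate={cc: suicide_rate[cc] for cc in countries if reports_suicide[cc]},
        late_ratio={cc: late_ratio[cc] for cc in countries if reports_late[cc]},
    )
    truth.validate()
    return ds, truth


def truth_coverage_check(truth: SyntheticTruth, summaries) -> dict:
    """Fraction of true cause proportions inside the 80% UIs, by level.

    ``summaries`` is an iterable of summaries as produced by the
    aggregation step (on the non-HIV scale for comparability with the
    recorded truth). Returns, per level present, the empirical coverage,
    its Monte-Carlo standard error and the number of checks.
    """
    truth_by_level = {
        "country": {u: truth.p_country[truth.countries.index(u)] for u in truth.countries},
        "region": {u: truth.p_region[truth.regions.index(u)] for u in truth.regions},
        "global": {"global": truth.p_global},
    }
    hits: dict[str, list[bool]] = {}
    for s in summaries:
        if tuple(s.causes) != tuple(truth.causes):
            raise ValueError(
                f"cause ordering mismatch: summary {tuple(s.causes)} vs truth {tuple(truth.causes)}"
            )
        p_true = truth_by_level.get(s.level, {}).get(s.unit)
        if p_true is None:
            continue
        inside = (s.prop_q10 <= p_true) & (p_true <= s.prop_q90)
        hits.setdefault(s.level, []).extend(bool(b) for b in inside)
    report = {}
    for level, h in hits.items():
        n = len(h)
        cov = float(np.mean(h))
        report[level] = {
            "coverage": cov,
            "mc_se": float(math.sqrt(max(cov * (1 - cov), 1e-12) / n)),
            "n_checks": n,
        }
    return report
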