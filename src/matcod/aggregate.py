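"""From posterior composition draws to regional death counts and report tables.

Per posterior draw, a country's cause-of-death distribution (after
adding back HIV/AIDS-related indirect deaths from the envelope) is
multiplied by its envelope deaths to give deaths by cause; regional and
global draws are sums of country draws, and regional proportions are
ratio-of-sums per draw — which keeps count/percentage pairs consistent
within each draw and makes cause-specific deaths sum exactly to the
envelope at every level. Point estimates are posterior medians with 80%
uncertainty intervals from the 10th/90th percentiles, each quantity
summarised independently (so subgroup medians need not add up to the
parent's median — the published convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .causes import CAUSES, SUBGROUPS
from .io import Dataset, EnvelopeTable, SOURCE_TYPES
from .model import ModelConfig, PosteriorSamples, _fit_counts


def incorporate_hiv(
    p_draws: np.ndarray, h, causes: Sequence[str] = CAUSES
) -> np.ndarray:
    """Blend HIV/AIDS-related indirect deaths into composition draws.

    Every non-indirect cause is scaled by ``1 - h``; the indirect share
    becomes ``(1 - h) * p_indirect + h``. ``h`` may be a scalar or an
    array broadcastable over the draw dimensions.
    """
    h = np.asarray(h, dtype=float)
    if (h < 0).any() or (h > 1).any():
        raise ValueError("HIV proportion must lie in [0, 1]")
    p = np.asarray(p_draws, dtype=float)
    out = (1.0 - h)[..., None] * p if h.ndim else (1.0 - h) * p
    ind = list(causes).index("indirect")
    out[..., ind] += h
    return out


@dataclass
class RegionalSummary:
    """Posterior summary of one unit's cause distribution and death counts."""

    level: str  # country | region | global
    unit: str
    causes: tuple[str, ...]
    prop_median: np.ndarray
    prop_q10: np.ndarray
    prop_q90: np.ndarray
    deaths_median: np.ndarray
    deaths_q10: np.ndarray
    deaths_q90: np.ndarray
    envelope_deaths: float

    def __post_init__(self) -> None:
        for lo, mid, hi in (
            (self.prop_q10, self.prop_median, self.prop_q90),
            (self.deaths_q10, self.deaths_median, self.deaths_q90),
        ):
            if not ((lo <= mid + 1e-12).all() and (mid <= hi + 1e-12).all()):
                raise AssertionError("quantile ordering violated: need q10 <= median <= q90")
        if (self.prop_median < 0).any() or (self.prop_median > 1).any():
            raise AssertionError("summary proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.level,
                "unit": self.unit,
                "cause": self.causes,
                "prop_median": self.prop_median,
                "prop_q10": self.prop_q10,
                "prop_q90": self.prop_q90,
                "deaths_median": self.deaths_median,
                "deaths_q10": self.deaths_q10,
                "deaths_q90": self.deaths_q90,
                "envelope_deaths": self.envelope_deaths,
            }
        )


@dataclass
class AggregateResult:
    causes: tuple[str, ...]
    countries: list[str]
    regions: list[str]
    region_of_country: np.ndarray
    env_country: np.ndarray  # (C,)
    p_star: np.ndarray  # (S, C, K) compositions used (post HIV incorporation)
    country_deaths: np.ndarray  # (S, C, K)
    region_deaths: np.ndarray  # (S, R, K)
    global_deaths: np.ndarray  # (S, K)
    summaries: list[RegionalSummary] = field(default_factory=list)

    @property
    def env_region(self) -> np.ndarray:
        R = len(self.regions)
        out = np.zeros(R)
        np.add.at(out, self.region_of_country, self.env_country)
        return out

    def summary_for(self, level: str, unit: str) -> RegionalSummary:
        for s in self.summaries:
            if s.level == level and s.unit == unit:
                return s
        raise KeyError(f"no summary for {level} {unit!r}")


def _summarize(
    level: str,
    unit: str,
    causes: tuple[str, ...],
    prop_draws: np.ndarray,
    death_draws: np.ndarray,
    env: float,
) -> RegionalSummary:
    q = lambda x, v: np.quantile(x, v, axis=0)
    return RegionalSummary(
        level=level,
        unit=unit,
        causes=causes,
        prop_median=q(prop_draws, 0.5),
        prop_q10=q(prop_draws, 0.1),
        prop_q90=q(prop_draws, 0.9),
        deaths_median=q(death_draws, 0.5),
        deaths_q10=q(death_draws, 0.1),
        deaths_q90=q(death_draws, 0.9),
        envelope_deaths=float(env),
    )


def aggregate(
    ps: PosteriorSamples,
    env: EnvelopeTable,
    window: Optional[tuple[int, int]] = (2009, 2020),
    with_hiv: bool = True,
    levels: Sequence[str] = ("country", "region", "global"),
) -> AggregateResult:
    """Envelope-weighted aggregation of composition draws to death counts.

    Every target country must appear in the envelope over the analysis
    window; the estimated (time-constant) composition is applied to the
    country's summed envelope deaths, with the country's death-weighted
    HIV proportion incorporated when ``with_hiv`` is set.
    """
    ct = env.country_totals(window)
    missing = [c for c in ps.countries if c not in ct.index]
    if missing:
        raise ValueError(
            f"envelope has no records in window {window} for: {missing}"
        )
    env_c = ct.loc[ps.countries, "deaths"].to_numpy()
    h_c = ct.loc[ps.countries, "hiv_proportion"].to_numpy()

    P = ps.p_flat()  # (S, C, K)
    p_star = incorporate_hiv(P, h_c[None, :], ps.causes) if with_hiv else P
    country_deaths = env_c[None, :, None] * p_star
    R = len(ps.regions)
    S, C, K = p_star.shape
    region_deaths = np.zeros((S, R, K))
    np.add.at(region_deaths, (slice(None), ps.country_region_idx), country_deaths)
    global_deaths = country_deaths.sum(axis=1)

    res = AggregateResult(
        causes=ps.causes,
        countries=ps.countries,
        regions=ps.regions,
        region_of_country=ps.country_region_idx,
        env_country=env_c,
        p_star=p_star,
        country_deaths=country_deaths,
        region_deaths=region_deaths,
        global_deaths=global_deaths,
    )
    if "country" in levels:
        for i, c in enumerate(ps.countries):
            res.summaries.append(
                _summarize(
                    "country", c, ps.causes, p_star[:, i, :], country_deaths[:, i, :], env_c[i]
                )
            )
    env_r = res.env_region
    if "region" in levels:
        for r, rr in enumerate(ps.regions):
            res.summaries.append(
                _summarize(
                    "region",
                    rr,
                    ps.causes,
                    region_deaths[:, r, :] / env_r[r],
                    region_deaths[:, r, :],
                    env_r[r],
                )
            )
    if "global" in levels:
        res.summaries.append(
            _summarize(
                "global",
                "global",
                ps.causes,
                global_deaths / env_c.sum(),
                global_deaths,
                env_c.sum(),
            )
        )
    return res


# --------------------------------------------------------------------------
# subgroup splits


@dataclass
class SubgroupSplit:
    """Per-country simplex draws over one parent cause's subgroups."""

    parent: str
    labels: tuple[str, ...]
    countries: list[str]
    draws: np.ndarray  # (chains, n_draws, C, n_sub)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def draws_flat(self) -> np.ndarray:
        return self.draws.reshape(-1, len(self.countries), len(self.labels))

    def validate(self) -> None:
        f = self.draws_flat()
        if not np.allclose(f.sum(axis=-1), 1.0, atol=1e-10):
            raise AssertionError("subgroup split draws must sum to 1 per draw")


def fit_subgroup_model(
    ds: Dataset, parent: str, cfg: Optional[ModelConfig] = None
) -> SubgroupSplit:
    """Hierarchical multinomial over one parent cause's subgroup set.

    Uses only observations that report subgroup counts for ``parent``,
    conditional on the parent cause: the multinomial size is the number
    of parent deaths with a subgroup assigned, and the partial-assignment
    inflation uses the observation's total parent count. With no
    subgroup data anywhere the fit degenerates (with a warning) to the
    prior hierarchy, i.e. region splits fall back to the global prior.
    """
    if parent not in SUBGROUPS:
        raise ValueError(f"cause {parent!r} has no subgroup scheme")
    labels = SUBGROUPS[parent]
    cfg = cfg or ModelConfig()
    base = ModelConfig(**{**cfg.__dict__, "reference_cause": labels[-1]})
    base.validate()

    countries = ds.countries
    regions = ds.regions
    c_index = {c: i for i, c in enumerate(countries)}
    r_index = {r: i for i, r in enumerate(regions)}
    region_of_country = np.array([r_index[ds.region_map[c]] for c in countries])
    parent_idx = CAUSES.index(parent)

    rows, totals, cidx, sidx = [], [], [], []
    for o in ds.observations:
        if not o.subgroup_counts or parent not in o.subgroup_counts:
            continue
        sub = o.subgroup_counts[parent]
        if sub.sum() == 0:
            continue
        rows.append(sub)
        totals.append(max(float(o.counts[parent_idx]), float(sub.sum())))
        cidx.append(c_index[o.country])
        sidx.append(SOURCE_TYPES.index(o.source_type))
    if not rows:
        warnings.warn(
            f"no subgroup data for {parent!r} anywhere; splits fall back to the "
            "prior hierarchy",
            stacklevel=2,
        )
        counts = np.zeros((0, len(labels)), dtype=np.int64)
        totals_arr = np.zeros(0)
        cidx_arr = np.zeros(0, dtype=int)
        sidx_arr = np.zeros(0, dtype=int)
    else:
        counts = np.asarray(rows, dtype=np.int64)
        totals_arr = np.asarray(totals, dtype=float)
        cidx_arr = np.asarray(cidx, dtype=int)
        sidx_arr = np.asarray(sidx, dtype=int)

    res = _fit_counts(
        counts,
        totals_arr,
        cidx_arr,
        sidx_arr,
        region_of_country,
        len(regions),
        tuple(labels),
        labels[-1],
        base,
    )
    split = SubgroupSplit(
        parent=parent,
        labels=tuple(labels),
        countries=countries,
        draws=res["p"],
        converged=True,
    )
    split.validate()
    return split


@dataclass
class SubgroupSummary:
    level: str
    unit: str
    parent: str
    subgroup: str
    prop_median: float  # share of all maternal deaths in the unit
    prop_q10: float
    prop_q90: float
    deaths_median: float
    deaths_q10: float
    deaths_q90: float


def split_subgroups(
    agg: AggregateResult, splits: Union[SubgroupSplit, Sequence[SubgroupSplit]]
) -> list[SubgroupSummary]:
    """Extend aggregated summaries with per-subgroup death counts and shares.

    Subgroup deaths are exact per draw (parent deaths × subgroup
    fraction, summing to the parent within each draw); each subgroup is
    then summarised independently, so summary medians need not add up to
    the parent's median.
    """
    if isinstance(splits, SubgroupSplit):
        splits = [splits]
    out: list[SubgroupSummary] = []
    S = agg.country_deaths.shape[0]
    env_r = agg.env_region
    env_g = agg.env_country.sum()
    for split in splits:
        f = split.draws_flat()  # (S', C, n_sub)
        if f.shape[0] != S or split.countries != agg.countries:
            raise ValueError(
                "subgroup split draws are not aligned with the aggregated draws "
                f"(draws {f.shape[0]} vs {S})"
            )
        k = list(agg.causes).index(split.parent)
        d_parent = agg.country_deaths[:, :, k]  # (S, C)
        for g, label in enumerate(split.labels):
            d_sub_c = d_parent * f[:, :, g]  # (S, C)
            d_sub_r = np.zeros((S, len(agg.regions)))
            np.add.at(d_sub_r, (slice(None), agg.region_of_country), d_sub_c)
            d_sub_g = d_sub_c.sum(axis=1)
            units = (
                [("global", "global", d_sub_g, env_g)]
                + [
                    ("region", rr, d_sub_r[:, r], env_r[r])
                    for r, rr in enumerate(agg.regions)
                ]
            )
            for level, unit, draws_u, env_u in units:
                q = lambda v: float(np.quantile(draws_u, v))
                out.append(
                    SubgroupSummary(
                        level=level,
                        unit=unit,
                        parent=split.parent,
                        subgroup=label,
                        prop_median=q(0.5) / env_u,
                        prop_q10=q(0.1) / env_u,
                        prop_q90=q(0.9) / env_u,
                        deaths_median=q(0.5),
                        deaths_q10=q(0.1),
                        deaths_q90=q(0.9),
                    )
                )
    return out


def subgroup_table(summaries: Sequence[SubgroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
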