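"""Descriptive (non-modelled) analyses: maternal suicide and late maternal deaths.

Both quantities derive directly from observed data, so no uncertainty
intervals are attached. Maternal suicide counts are usable only from
specialised sources (confidential enquiries, national reports,
subnational studies): suicide codes in routine CRVS data do not record
pregnancy status, so CRVS rows never contribute. A country's suicide
proportion pools its eligible observations (summed suicides over summed
maternal deaths); only countries recording at least one maternal
suicide enter the report. The late-maternal-death analysis reports, per
country, the ratio of deaths occurring 42 days to 1 year after the end
of pregnancy to maternal deaths up to 42 days — a ratio that may exceed
1. Regional figures are unweighted means over contributing countries; a
death-count-weighted variant is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import Observation


def format_ratio(r: float) -> str:
    """Report-table rendering: values below 0.005 print as "<0·01"."""
    if r < 0:
        raise ValueError("ratio cannot be negative")
    if r < 0.005:
        return "<0·01"
    return f"{r:.2f}".replace(".", "·")


@dataclass
class SuicideReport:
    """Countries recording >=1 maternal suicide, and their pooled proportions."""

    country_proportions: dict[str, float]  # country -> suicides / all maternal deaths
    by_region: dict[str, dict] = field(default_factory=dict)

    @property
    def n_countries(self) -> int:
        return len(self.country_proportions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": region,
                "n_countries": d["n_countries"],
                "countries": ";".join(d["countries"]),
                "average_proportion": d["average_proportion"],
            }
            for region, d in sorted(self.by_region.items())
        ]
        return pd.DataFrame(rows)


def suicide_summary(
    observations: Iterable[Observation],
    region_map: Mapping[str, str],
    weighted: bool = False,
) -> SuicideReport:
    """Suicide proportions per country and their regional averages.

    Pools each country's eligible (non-CRVS) observations by summing
    numerators and denominators; countries with zero recorded suicides
    are excluded. Regional averages are unweighted country means unless
    ``weighted`` (by the country's pooled maternal deaths) is requested.
    """
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    for o in observations:
        if o.source_type == "crvs" or o.suicide_count is None:
            continue
        num[o.country] = num.get(o.country, 0) + o.suicide_count
        den[o.country] = den.get(o.country, 0) + o.n_total
    props = {
        c: num[c] / den[c] for c in num if num[c] >= 1 and den[c] > 0
    }
    by_region: dict[str, dict] = {}
    for c, p in sorted(props.items()):
        by_region.setdefault(region_map[c], {"countries": [], "props": [], "dens": []})
        by_region[region_map[c]]["countries"].append(c)
        by_region[region_map[c]]["props"].append(p)
        by_region[region_map[c]]["dens"].append(den[c])
    for region, d in by_region.items():
        w = np.asarray(d.pop("dens"), dtype=float)
        p = np.asarray(d.pop("props"), dtype=float)
        d["n_countries"] = len(d["countries"])
        d["average_proportion"] = float(np.average(p, weights=w if weighted else None))
    return SuicideReport(country_proportions=props, by_region=by_region)


@dataclass
class LateRatioReport:
    """Ratio of late maternal deaths (42 days–1 year) to deaths up to 42 days."""

    country_ratios: dict[str, float]
    by_region: dict[str, dict] = field(default_factory=dict)

    @property
    def n_countries(self) -> int:
        return len(self.country_ratios)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": region,
                "n_countries": d["n_countries"],
                "countries": ";".join(d["countries"]),
                "mean_ratio": d["mean_ratio"],
                "mean_ratio_formatted": format_ratio(d["mean_ratio"]),
            }
            for region, d in sorted(self.by_region.items())
        ]
        return pd.DataFrame(rows)


def late_ratio_summary(
    observations: Iterable[Observation],
    region_map: Mapping[str, str],
    weighted: bool = False,
) -> LateRatioReport:
    """Per-country late-to-early death ratios and their regional means.

    A country contributes if any of its observations reports a late
    count (zero included); its ratio pools summed late deaths over
    summed maternal deaths up to 42 days. Countries whose reporting
    observations carry no maternal deaths are excluded with a warning.
    Ratios above 1 (more late deaths than deaths up to day 42) are
    legitimate and preserved.
    """
    late: dict[str, int] = {}
    early: dict[str, int] = {}
    for o in observations:
        if o.late_count is None:
            continue
        late[o.country] = late.get(o.country, 0) + o.late_count
        early[o.country] = early.get(o.country, 0) + o.n_total
    ratios: dict[str, float] = {}
    for c in late:
        if early[c] <= 0:
            warnings.warn(
                f"country {c} reports late deaths but no maternal deaths up to "
                "42 days; excluded from the late-ratio report",
                stacklevel=2,
            )
            continue
        ratios[c] = late[c] / early[c]
    by_region: dict[str, dict] = {}
    for c, r in sorted(ratios.items()):
        by_region.setdefault(region_map[c], {"countries": [], "ratios": [], "dens": []})
        by_region[region_map[c]]["countries"].append(c)
        by_region[region_map[c]]["ratios"].append(r)
        by_region[region_map[c]]["dens"].append(early[c])
    for region, d in by_region.items():
        w = np.asarray(d.pop("dens"), dtype=float)
        r = np.asarray(d.pop("ratios"), dtype=float)
        d["n_countries"] = len(d["countries"])
        d["mean_ratio"] = float(np.average(r, weights=w if weighted else None))
    return LateRatioReport(country_ratios=ratios, by_region=by_region)
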