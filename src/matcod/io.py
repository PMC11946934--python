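"""Reading, validation and normalisation of observation and envelope tables.

An *observation* is one data source's cause-of-death counts for a
country-period: a row of counts over the seven cause groups, the number
of deaths with an assigned cause (``n_assigned``, the sum of those
counts) and the total maternal deaths the source identified
(``n_total`` ≥ ``n_assigned``), plus optional subgroup, suicide and
late-death counts. Sources come in four reliability tiers, from
confidential enquiries (most trusted) down to subnational studies.

The *envelope* is the exogenous per-country-year table of total
maternal deaths and the HIV-attributable proportion, emulating the UN
interagency (MMEIG) estimates that the analysis consumes but never
re-estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .causes import CAUSES, SUBGROUPS

#: Source reliability tiers, most to least trusted.
SOURCE_TYPES: tuple[str, ...] = (
    "confidential_enquiry",
    "crvs",
    "national_report",
    "subnational_study",
)

_SUBGROUP_COLS = {
    "haemorrhage": ("haem_ap", "haem_ip", "haem_pp"),
    "sepsis": ("sep_ap", "sep_ip", "sep_pp"),
    "other_direct": ("od_anaesthesia", "od_obstructed", "od_trauma", "od_other"),
}

OBS_REQUIRED_COLS = (
    ["country", "region", "period_start", "period_end", "source_type"]
    + list(CAUSES)
    + ["n_total"]
)
OBS_OPTIONAL_COLS = [c for cols in _SUBGROUP_COLS.values() for c in cols] + [
    "suicide",
    "late",
]
ENV_COLS = ("country", "year", "deaths", "hiv_proportion")


class ValidationError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass
class Observation:
    country: str
    region: str
    period_start: int
    period_end: int
    source_type: str
    counts: np.ndarray  # length-7 non-negative ints, CAUSES order
    n_total: int
    subgroup_counts: Optional[dict[str, np.ndarray]] = None
    suicide_count: Optional[int] = None
    late_count: Optional[int] = None

    @property
    def n_assigned(self) -> int:
        return int(self.counts.sum())

    def midpoint(self) -> float:
        return 0.5 * (self.period_start + self.period_end)

    def eligible(self, window: tuple[int, int] = (2009, 2020)) -> bool:
        """Inclusion rule: the midpoint of the reference period lies in the window."""
        return window[0] <= self.midpoint() <= window[1]

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.source_type not in SOURCE_TYPES:
            problems.append(
                f"unknown source_type {self.source_type!r} "
                f"(single-facility and other non-tier sources are excluded)"
            )
        if self.counts.shape != (len(CAUSES),):
            problems.append("counts must have one entry per cause group")
            return problems
        if (self.counts < 0).any():
            problems.append("negative cause count")
        if self.n_total < self.n_assigned:
            problems.append(
                f"assigned-count mismatch: n_total={self.n_total} < "
                f"n_assigned={self.n_assigned}"
            )
        if self.period_start > self.period_end:
            problems.append("period_start > period_end")
        if self.subgroup_counts is not None:
            for parent, sub in self.subgroup_counts.items():
                if parent not in SUBGROUPS:
                    problems.append(f"subgroup counts for non-subdivided group {parent!r}")
                    continue
                if (sub < 0).any():
                    problems.append(f"negative subgroup count under {parent!r}")
                parent_n = self.counts[CAUSES.index(parent)]
                if sub.sum() > parent_n:
                    problems.append(
                        f"subgroup counts under {parent!r} sum to {int(sub.sum())} "
                        f"> parent count {int(parent_n)}"
                    )
        if self.suicide_count is not None and self.suicide_count < 0:
            problems.append("negative suicide count")
        if self.late_count is not None and self.late_count < 0:
            problems.append("negative late-death count")
        return problems


@dataclass
class EnvelopeTable:
    """Per country-year total maternal deaths and HIV-attributable proportion."""

    table: pd.DataFrame  # columns: country, year, deaths, hiv_proportion

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ENV_COLS if c not in t.columns]
        if missing:
            raise ValidationError(f"envelope missing columns: {missing}")
        problems = []
        if t.duplicated(["country", "year"]).any():
            dups = t[t.duplicated(["country", "year"], keep=False)]
            keys = sorted(set(map(tuple, dups[["country", "year"]].values)))
            problems.append(f"duplicated (country, year) records: {keys}")
        if (t["deaths"] < 0).any():
            problems.append("negative envelope deaths")
        bad_h = t[(t["hiv_proportion"] < 0) | (t["hiv_proportion"] > 1)]
        if len(bad_h):
            problems.append(
                f"hiv_proportion outside [0, 1] for {len(bad_h)} record(s), "
                f"e.g. {bad_h.iloc[0]['country']} {int(bad_h.iloc[0]['year'])}"
            )
        if problems:
            raise ValidationError("; ".join(problems))
        self.table = t.reset_index(drop=True)

    def countries(self) -> list[str]:
        return sorted(self.table["country"].unique())

    def total_deaths(self, window: Optional[tuple[int, int]] = None) -> float:
        t = self.table
        if window is not None:
            t = t[(t["year"] >= window[0]) & (t["year"] <= window[1])]
        return float(t["deaths"].sum())

    def country_totals(self, window: Optional[tuple[int, int]] = None) -> pd.DataFrame:
        """Per-country envelope deaths and death-weighted HIV proportion."""
        t = self.table
        if window is not None:
            t = t[(t["year"] >= window[0]) & (t["year"] <= window[1])]
        g = t.groupby("country", sort=True)
        deaths = g["deaths"].sum()
        hiv = g.apply(
            lambda x: float(np.average(x["hiv_proportion"], weights=x["deaths"]))
            if x["deaths"].sum() > 0
            else float(x["hiv_proportion"].mean()),
            include_groups=False,
        )
        return pd.DataFrame({"deaths": deaths, "hiv_proportion": hiv})


@dataclass
class Dataset:
    observations: list[Observation]
    envelope: EnvelopeTable
    region_map: dict[str, str]
    window: tuple[int, int] = (2009, 2020)

    def __post_init__(self) -> None:
        missing = sorted({o.country for o in self.observations} - set(self.region_map))
        if missing:
            raise ValidationError(f"observations reference countries absent from region_map: {missing}")

    @property
    def countries(self) -> list[str]:
        """Estimation target set: every country in the region map, sorted."""
        return sorted(self.region_map)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.region_map.values()))


def default_region_map() -> dict[str, str]:
    """The shipped (editable) ISO3 → SDG-region lookup."""
    with resources.as_file(resources.files("matcod.data").joinpath("sdg_regions.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["country"], df["region"]))


def _obs_from_row(row: pd.Series) -> Observation:
    counts = np.array([int(row[c]) for c in CAUSES], dtype=np.int64)
    sub: dict[str, np.ndarray] = {}
    for parent, cols in _SUBGROUP_COLS.items():
        if all(c in row.index and pd.notna(row[c]) for c in cols):
            sub[parent] = np.array([int(row[c]) for c in cols], dtype=np.int64)
    suicide = int(row["suicide"]) if "suicide" in row.index and pd.notna(row["suicide"]) else None
    late = int(row["late"]) if "late" in row.index and pd.notna(row["late"]) else None
    return Observation(
        country=str(row["country"]),
        region=str(row["region"]),
        period_start=int(row["period_start"]),
        period_end=int(row["period_end"]),
        source_type=str(row["source_type"]),
        counts=counts,
        n_total=int(row["n_total"]),
        subgroup_counts=sub or None,
        suicide_count=suicide,
        late_count=late,
    )


def read_observations(path, scheme=None) -> list[Observation]:
    """Read and validate an observation CSV; rejects with row-numbered diagnostics.

    ``scheme`` is accepted for interface symmetry (the CSV is already in
    grouped form); it is unused.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"observation table missing columns: {missing}")
    observations: list[Observation] = []
    errors: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based incl. header
        try:
            obs = _obs_from_row(row)
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: unparseable ({exc})")
            continue
        problems = obs.validate()
        if problems:
            errors.extend(f"row {i}: {p}" for p in problems)
        else:
            observations.append(obs)
    if errors:
        raise ValidationError("invalid observation rows:\n" + "\n".join(errors))
    return observations


def read_envelope(path) -> EnvelopeTable:
    df = pd.read_csv(path)
    missing = [c for c in ENV_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"envelope table missing columns: {missing}")
    return EnvelopeTable(df[list(ENV_COLS)].copy())


def write_observations(observations: Iterable[Observation], path) -> None:
    rows = []
    for o in observations:
        row: dict = {
            "country": o.country,
            "region": o.region,
            "period_start": o.period_start,
            "period_end": o.period_end,
            "source_type": o.source_type,
            **{c: int(o.counts[i]) for i, c in enumerate(CAUSES)},
            "n_total": o.n_total,
        }
        if o.subgroup_counts:
            for parent, cols in _SUBGROUP_COLS.items():
                if parent in o.subgroup_counts:
                    for c, v in zip(cols, o.subgroup_counts[parent]):
                        row[c] = int(v)
        if o.suicide_count is not None:
            row["suicide"] = o.suicide_count
        if o.late_count is not None:
            row["late"] = o.late_count
        rows.append(row)
    cols = OBS_REQUIRED_COLS + [c for c in OBS_OPTIONAL_COLS if any(c in r for r in rows)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_envelope(env: EnvelopeTable, path) -> None:
    env.table.to_csv(path, index=False)


def apply_source_preference(
    observations: list[Observation], mode: str = "drop"
) -> list[Observation]:
    """Resolve CRVS vs confidential-enquiry overlap for the same country-period.

    Where a country has a confidential enquiry, overlapping CRVS rows are
    preferred away: dropped (default, mirroring the study's rule) or
    down-weighted by reclassifying them into the least-trusted tier so
    they keep contributing with the widest source uncertainty.
    """
    if mode not in ("drop", "downweight"):
        raise ValueError("mode must be 'drop' or 'downweight'")
    enquiry_spans: dict[str, list[tuple[int, int]]] = {}
    for o in observations:
        if o.source_type == "confidential_enquiry":
            enquiry_spans.setdefault(o.country, []).append((o.period_start, o.period_end))
    out: list[Observation] = []
    for o in observations:
        overlap = o.source_type == "crvs" and any(
            not (o.period_end < s or o.period_start > e)
            for s, e in enquiry_spans.get(o.country, [])
        )
        if not overlap:
            out.append(o)
        elif mode == "downweight":
            out.append(replace(o, source_type="subnational_study"))
    return out


def dataset_summary(ds: Dataset) -> dict:
    """Headline counts: countries with data, country-years, input deaths, coverage.

    Coverage is the percentage of envelope deaths (over the analysis
    window) represented in the input data, reported to one decimal.
    """
    if not ds.observations:
        raise ValidationError("dataset has no observations")
    country_years = set()
    for o in ds.observations:
        for y in range(o.period_start, o.period_end + 1):
            country_years.add((o.country, y))
    total_input = sum(o.n_total for o in ds.observations)
    total_env = ds.envelope.total_deaths(ds.window)
    if total_env <= 0:
        raise ValidationError("envelope total is zero over the analysis window")
    return {
        "n_countries_with_data": len({o.country for o in ds.observations}),
        "n_country_years": len(country_years),
        "total_input_deaths": int(total_input),
        "total_envelope_deaths": float(total_env),
        "coverage_pct": round(100.0 * total_input / total_env, 1),
    }
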