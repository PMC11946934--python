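"""Cause-of-death taxonomy for maternal mortality analysis.

Maternal deaths are grouped into seven mutually exclusive main causes:
abortion (including ectopic pregnancy and other abortive outcomes),
embolism, haemorrhage, hypertensive disorders of pregnancy,
pregnancy-related sepsis, other direct obstetric causes, and indirect
obstetric causes (pre-existing disease aggravated by pregnancy).
Haemorrhage and sepsis are further split by timing relative to the end
of pregnancy (antepartum / intrapartum / postpartum); other direct
causes are split into anaesthesia complications, obstructed labour,
obstetric trauma, and other.

Two special labels live *outside* the seven-group simplex: ``suicide``
(maternal suicide, reported descriptively because routine vital
registration cannot link suicide to pregnancy status) and ``late``
(deaths from obstetric causes more than 42 days but less than one year
after the end of pregnancy, ICD-10 O96/O97).

The ICD-10 → group mapping ships as a versioned, user-replaceable CSV
(``data/icd10_map_default.csv``); assignment uses longest-prefix match
on dot-stripped codes. Codes outside the mapped range return
``not_maternal``.

The tuple :data:`CAUSES` fixes the coordinate order used everywhere
downstream (simulator, model, aggregation tables).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Optional, Sequence

#: Fixed coordinate order of the seven modelled cause groups.
CAUSES: tuple[str, ...] = (
    "abortion",
    "embolism",
    "haemorrhage",
    "hypertension",
    "sepsis",
    "other_direct",
    "indirect",
)

DISPLAY_NAMES: dict[str, str] = {
    "abortion": "Abortion and abortive outcomes",
    "embolism": "Embolism",
    "haemorrhage": "Haemorrhage",
    "hypertension": "Hypertensive disorders",
    "sepsis": "Pregnancy-related sepsis",
    "other_direct": "Other direct causes",
    "indirect": "Indirect causes",
}

TIMING_SUBGROUPS: tuple[str, ...] = ("antepartum", "intrapartum", "postpartum")
OTHER_DIRECT_SUBGROUPS: tuple[str, ...] = (
    "anaesthesia",
    "obstructed_labour",
    "obstetric_trauma",
    "other",
)

#: Parents that carry a subgroup split, with their subgroup coordinate order.
SUBGROUPS: dict[str, tuple[str, ...]] = {
    "haemorrhage": TIMING_SUBGROUPS,
    "sepsis": TIMING_SUBGROUPS,
    "other_direct": OTHER_DIRECT_SUBGROUPS,
}

#: Labels outside the modelled simplex.
SUICIDE = "suicide"
LATE = "late"
NOT_MATERNAL = "not_maternal"
SPECIAL_LABELS: tuple[str, ...] = (SUICIDE, LATE)

#: Default reference coordinate for additive log-ratio transforms.
DEFAULT_REFERENCE = "other_direct"

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")


class Assignment(NamedTuple):
    """Result of mapping one ICD-10 code.

    ``group`` is one of :data:`CAUSES`, ``suicide``, ``late`` or
    ``not_maternal``; ``subgroup`` is set only for groups that carry one.
    """

    group: str
    subgroup: Optional[str] = None


@dataclass(frozen=True)
class MappingEntry:
    prefix: str
    group: str
    subgroup: Optional[str] = None


@dataclass
class IcdMapping:
    """A longest-prefix-match table from ICD-10 codes to cause groups."""

    entries: tuple[MappingEntry, ...]
    version: str = "unversioned"
    _by_prefix: dict[str, MappingEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_prefix: dict[str, MappingEntry] = {}
        for e in self.entries:
            # duplicates surface through validate_scheme; last-wins here
            # would hide them, so keep the first occurrence deterministic
            by_prefix.setdefault(e.prefix, e)
        object.__setattr__(self, "_by_prefix", by_prefix)

    @classmethod
    def from_csv(cls, path) -> "IcdMapping":
        version = "unversioned"
        entries: list[MappingEntry] = []
        with open(path, newline="") as fh:
            first = fh.readline()
            if first.startswith("#"):
                m = re.search(r"version\s*=\s*(\S+)", first)
                if m:
                    version = m.group(1)
            else:
                fh.seek(0)
            for row in csv.DictReader(fh):
                sub = row.get("subgroup") or None
                entries.append(
                    MappingEntry(row["code_prefix"].strip().upper(), row["group"].strip(), sub)
                )
        return cls(entries=tuple(entries), version=version)

    def lookup(self, normalized_code: str) -> Optional[MappingEntry]:
        """Longest-prefix match; ``None`` when no prefix matches."""
        for ln in range(len(normalized_code), 0, -1):
            e = self._by_prefix.get(normalized_code[:ln])
            if e is not None:
                return e
        return None


def default_mapping() -> IcdMapping:
    """The shipped default ICD-10 mapping (reconstructed from chapter-O block titles)."""
    with resources.as_file(
        resources.files("matcod.data").joinpath("icd10_map_default.csv")
    ) as p:
        return IcdMapping.from_csv(p)


def normalize_code(code: str) -> str:
    """Uppercase and strip the dot from an ICD-10 code; validate its shape."""
    if not isinstance(code, str) or not code.strip():
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    c = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return c


def map_icd10(code: str, mapping: Optional[IcdMapping] = None) -> Assignment:
    """Assign an ICD-10 code to a cause group (or a special label).

    Uses deterministic longest-prefix match against ``mapping`` (the
    shipped default when omitted). Codes with no matching prefix — e.g.
    any code outside the maternal range — return ``not_maternal``.
    """
    if mapping is None:
        mapping = default_mapping()
    c = normalize_code(code)
    entry = mapping.lookup(c)
    if entry is None:
        return Assignment(NOT_MATERNAL)
    return Assignment(entry.group, entry.subgroup)


_VALID_GROUPS = set(CAUSES) | set(SPECIAL_LABELS)


def validate_scheme(mapping: IcdMapping) -> list[str]:
    """Check mapping invariants; returns human-readable violations (empty = valid).

    Checks: no prefix appears twice; group labels are known; subgroups
    belong to their assigned group; every 3-character code O00–O99
    resolves to one of the seven groups, ``suicide`` or ``late``.
    """
    violations: list[str] = []
    seen: dict[str, MappingEntry] = {}
    for e in mapping.entries:
        if e.prefix in seen and seen[e.prefix] != e:
            violations.append(
                f"duplicate code prefix {e.prefix!r}: maps to both "
                f"{seen[e.prefix].group!r} and {e.group!r}"
            )
        seen.setdefault(e.prefix, e)
        if e.group not in _VALID_GROUPS:
            violations.append(f"unknown group {e.group!r} for prefix {e.prefix!r}")
        if e.subgroup is not None:
            allowed = SUBGROUPS.get(e.group, ())
            if e.subgroup not in allowed:
                violations.append(
                    f"subgroup {e.subgroup!r} not valid for group {e.group!r} "
                    f"(prefix {e.prefix!r})"
                )
    for i in range(100):
        code = f"O{i:02d}"
        entry = mapping.lookup(code)
        if entry is None:
            violations.append(f"chapter-O coverage gap: {code} has no mapping")
        elif entry.group not in _VALID_GROUPS:
            violations.append(f"chapter-O code {code} maps to invalid group {entry.group!r}")
    return violations


def cause_index(cause: str) -> int:
    return CAUSES.index(cause)
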