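"""Domain types shared by every pipeline stage.

The data model mirrors the structure of a spontaneous-reporting database
such as FAERS: a safety *report* (one patient case, possibly present in
several versions) carries demographics, one or more drug entries with a
reporter-assigned role code, one or more adverse-event entries coded as
MedDRA-like preferred terms (PT), and outcome codes.  A small two-level
vocabulary maps each PT to a system organ class (SOC) and records the
synonym set (generic + brand names) of each canonical drug.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

ROLE_CODES = ("PS", "SS", "C", "I")
"""Reporter-assigned drug roles: primary suspect, secondary suspect,
concomitant, interacting."""

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "OT")
"""Case outcomes: death, life-threatening, hospitalization (initial or
prolonged), disability, other."""


class VocabularyError(ValueError):
    """Raised for malformed or contradictory vocabulary files."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report, name kept verbatim as reported."""

    drug_name: str
    role_code: str

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(
                f"unknown role code {self.role_code!r}; expected one of {ROLE_CODES}"
            )


@dataclass(frozen=True)
class EventEntry:
    """One adverse-event row of a report, coded as a preferred term."""

    pt_code: str
    pt_name: str


@dataclass
class AEReport:
    """One safety report (a single version of a case).

    ``case_id`` plus ``version`` identifies a raw record; after
    deduplication each ``case_id`` appears once.
    """

    case_id: str
    version: int
    receipt_date: _dt.date
    gender: str  # "male" | "female" | "unknown"
    age_years: float | None
    country: str | None
    outcome_codes: frozenset[str]
    drugs: list[DrugEntry]
    events: list[EventEntry]

    def __post_init__(self) -> None:
        if self.version < 0:
            raise ValueError("version must be non-negative")
        if self.gender not in ("male", "female", "unknown"):
            raise ValueError(f"gender must be male/female/unknown, got {self.gender!r}")
        if self.age_years is not None and not (0 <= self.age_years <= 130):
            raise ValueError(f"age_years out of [0, 130]: {self.age_years}")
        bad = set(self.outcome_codes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown outcome codes: {sorted(bad)}")
        if not self.drugs:
            raise ValueError("a report needs at least one drug entry")
        if not self.events:
            raise ValueError("a report needs at least one event entry")

    def pt_codes(self) -> frozenset[str]:
        """Distinct PT codes of this report (a PT listed twice counts once)."""
        return frozenset(e.pt_code for e in self.events)

    def has_drug(self, synonyms: Iterable[str], roles: Iterable[str]) -> bool:
        """True if any drug entry matches a synonym (case-insensitive,
        trimmed) with a role in ``roles``."""
        syn = {s.strip().casefold() for s in synonyms}
        roleset = set(roles)
        return any(
            d.drug_name.strip().casefold() in syn and d.role_code in roleset
            for d in self.drugs
        )


@dataclass
class Vocabulary:
    """Two-level MedDRA-like vocabulary: PT -> SOC plus drug synonyms.

    Codes, not names, are the join keys; PT names are matched
    case-insensitively after trimming wherever a name lookup is needed.
    """

    pt_to_soc: dict[str, str]
    pt_names: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, frozenset[str]] = field(default_factory=dict)

    def soc_of(self, pt_code: str) -> str:
        try:
            return self.pt_to_soc[pt_code]
        except KeyError:
            raise VocabularyError(f"PT code {pt_code!r} not in vocabulary") from None

    def pt_name(self, pt_code: str) -> str:
        return self.pt_names.get(pt_code, pt_code)

    @property
    def soc_names(self) -> frozenset[str]:
        return frozenset(self.pt_to_soc.values())

    def synonyms_of(self, canonical: str) -> frozenset[str]:
        key = canonical.strip().casefold()
        for name, variants in self.synonyms.items():
            if name.strip().casefold() == key:
                return variants
        return frozenset({canonical})


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report-level contingency table for one (drug, event) pair.

    ``a``: reports with the target drug and the event; ``b``: target drug
    without the event; ``c``: event without the target drug; ``d``:
    neither.  ``n`` is the full deduplicated in-window database size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalStats:
    """Disproportionality results for one (drug, PT) pair.

    ``ror``/``ci_low``/``ci_high`` are None when the Wald estimate is not
    estimable (a zero cell).  ``ic`` is the posterior mean information
    component E(IC) in bits and ``ic_2sd`` is E(IC) - 2*sqrt(V(IC)).
    ``signal`` is the dual-positivity verdict: both the ROR criterion
    (a >= 3 and lower CI bound > 1) and the BCPNN criterion (IC-2SD > 0)
    must hold.
    """

    ror: float | None
    ci_low: float | None
    ci_high: float | None
    ic: float
    ic_2sd: float
    ror_positive: bool
    bcpnn_positive: bool
    signal: bool


_PT_SECTION = "[pt_to_soc]"
_SYN_SECTION = "[synonyms]"


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Read a sectioned TSV vocabulary file.

    The file holds a ``[pt_to_soc]`` section (pt_code, pt_name, soc_name)
    and a ``[synonyms]`` section (canonical_name, variant).  A PT code
    listed under two different SOCs is a contradiction and rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vocabulary file not found: {path}")
    pt_to_soc: dict[str, str] = {}
    pt_names: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in (_PT_SECTION, _SYN_SECTION):
            section = line.strip()
            continue
        if section is None:
            raise VocabularyError(f"{path}:{lineno}: data before any section header")
        fields = [f.strip() for f in line.split("\t")]
        if section == _PT_SECTION:
            if fields[0] == "pt_code":  # header row
                continue
            if len(fields) != 3:
                raise VocabularyError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            code, name, soc = fields
            if code in pt_to_soc and pt_to_soc[code] != soc:
                raise VocabularyError(
                    f"PT {code!r} mapped to two SOCs: {pt_to_soc[code]!r} and {soc!r}"
                )
            if code in pt_to_soc:
                raise VocabularyError(f"duplicate PT code {code!r}")
            pt_to_soc[code] = soc
            pt_names[code] = name
        else:
            if fields[0] == "canonical_name":
                continue
            if len(fields) != 2:
                raise VocabularyError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            canonical, variant = fields
            synonyms.setdefault(canonical, set()).add(variant)
    return Vocabulary(
        pt_to_soc=pt_to_soc,
        pt_names=pt_names,
        synonyms={k: frozenset(v) for k, v in synonyms.items()},
    )


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Write a vocabulary in the sectioned TSV format read by
    :func:`load_vocabulary` (round-trips losslessly)."""
    lines = [_PT_SECTION, "pt_code\tpt_name\tsoc_name"]
    for code in sorted(vocab.pt_to_soc):
        lines.append(f"{code}\t{vocab.pt_name(code)}\t{vocab.pt_to_soc[code]}")
    lines.append(_SYN_SECTION)
    lines.append("canonical_name\tvariant")
    for canonical in sorted(vocab.synonyms):
        for variant in sorted(vocab.synonyms[canonical]):
            lines.append(f"{canonical}\t{variant}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_vocabulary() -> Vocabulary:
    """The bundled toy vocabulary: 69 PTs across 17 SOCs plus the
    omadacycline/nuzyra synonym pair."""
    ref = resources.files("pvsignal.data").joinpath("default_vocabulary.tsv")
    with resources.as_file(ref) as p:
        return load_vocabulary(p)
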