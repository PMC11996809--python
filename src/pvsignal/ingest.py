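"""Reading report tables, deduplication, inclusion criteria and the
clinical-characteristics summary.

The inclusion criteria mirror standard spontaneous-report retrieval: a
report enters the analysis set when its receipt date falls inside the
study window and the target drug appears with role primary suspect (PS)
or secondary suspect (SS) under any of its synonyms.  Reports where the
target appears only as concomitant or interacting are excluded.

A case present in several versions is reduced to one report per case id:
the highest version wins, ties broken by latest receipt date, then by the
full field tuple for a stable ordering.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .model import AEReport, DrugEntry, EventEntry, Vocabulary
from .simulate import TABLE_FILES

AGE_BANDS = ("<18", "18-44", "45-64", "65-74", ">=75", "Unknown")

# Band edges are half-open: [18,45), [45,65), [65,75), [75,inf).
_BAND_EDGES = ((None, 18.0), (18.0, 45.0), (45.0, 65.0), (65.0, 75.0), (75.0, None))

# Severity precedence used when a report carries several outcome codes;
# each report contributes exactly one outcome to the summary.
OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "HO", "OT")
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization-initial or prolonged",
    "DS": "Disability",
    "OT": "Other",
}


class IngestError(ValueError):
    """Raised for structurally invalid report tables."""


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria for the analysis set."""

    drug_synonyms: frozenset[str]
    allowed_roles: frozenset[str] = frozenset({"PS", "SS"})
    window_start: _dt.date = _dt.date(2004, 1, 1)
    window_end: _dt.date = _dt.date(2024, 3, 31)

    def __post_init__(self) -> None:
        if not self.drug_synonyms:
            raise ValueError("drug_synonyms must be non-empty")
        if not self.allowed_roles <= {"PS", "SS"}:
            raise ValueError("allowed_roles must be a subset of {PS, SS}")
        if self.window_start > self.window_end:
            raise ValueError("window_start must not exceed window_end")


@dataclass
class DemographicSummary:
    """Counts and percentages per category, in the style of a clinical-
    characteristics table.  Percentages use the analysis-set size as the
    denominator and are rounded half-up to 2 decimals."""

    total: int
    gender: dict[str, tuple[int, float]] = field(default_factory=dict)
    age_band: dict[str, tuple[int, float]] = field(default_factory=dict)
    outcome: dict[str, tuple[int, float]] = field(default_factory=dict)
    country: dict[str, tuple[int, float]] = field(default_factory=dict)
    year: dict[int, tuple[int, float]] = field(default_factory=dict)


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals."""
    if total == 0:
        raise ZeroDivisionError("total must be positive")
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def read_report_tables(data_dir: str | Path, vocabulary: Vocabulary) -> list[AEReport]:
    """Join the four flat tables back into raw AEReport records.

    Every DRUG/REAC/OUTC row must have a DEMO parent and every REAC PT
    code must resolve in the vocabulary; violations raise
    :class:`IngestError` naming the offending keys.
    """
    data_dir = Path(data_dir)
    frames = {}
    for name, filename in TABLE_FILES.items():
        path = data_dir / filename
        if not path.exists():
            raise FileNotFoundError(f"missing report table: {path}")
        frames[name] = pd.read_csv(
            path, sep="\t", dtype={"case_id": str}, keep_default_na=False, na_values=[]
        )
    demo = frames["demo"]
    keys = set(zip(demo["case_id"], demo["version"].astype(int)))
    if len(keys) != len(demo):
        raise IngestError("duplicate (case_id, version) keys in DEMO table")

    for name in ("drug", "reac", "outc"):
        child_keys = set(zip(frames[name]["case_id"], frames[name]["version"].astype(int)))
        orphans = sorted(child_keys - keys)
        if orphans:
            raise IngestError(
                f"{name.upper()} rows without a DEMO parent: {orphans[:10]}"
            )

    reac = frames["reac"]
    unknown_pts = sorted(set(reac["pt_code"].astype(str)) - set(vocabulary.pt_to_soc))
    if unknown_pts:
        raise IngestError(f"PT codes absent from vocabulary: {unknown_pts[:10]}")

    drugs_by_key: dict[tuple, list[DrugEntry]] = {}
    for row in frames["drug"].itertuples(index=False):
        drugs_by_key.setdefault((row.case_id, int(row.version)), []).append(
            DrugEntry(drug_name=str(row.drug_name), role_code=str(row.role_code))
        )
    events_by_key: dict[tuple, list[EventEntry]] = {}
    for row in reac.itertuples(index=False):
        events_by_key.setdefault((row.case_id, int(row.version)), []).append(
            EventEntry(pt_code=str(row.pt_code), pt_name=str(row.pt_name))
        )
    outcomes_by_key: dict[tuple, set[str]] = {}
    for row in frames["outc"].itertuples(index=False):
        outcomes_by_key.setdefault((row.case_id, int(row.version)), set()).add(
            str(row.outcome_code)
        )

    reports = []
    for row in demo.itertuples(index=False):
        key = (row.case_id, int(row.version))
        age_raw = str(row.age_years).strip()
        country_raw = str(row.country).strip()
        gender_raw = str(row.gender).strip().casefold()
        reports.append(
            AEReport(
                case_id=row.case_id,
                version=int(row.version),
                receipt_date=_dt.date.fromisoformat(str(row.receipt_date)),
                gender=gender_raw if gender_raw in ("male", "female") else "unknown",
                age_years=float(age_raw) if age_raw else None,
                country=country_raw or None,
                outcome_codes=frozenset(outcomes_by_key.get(key, set())),
                drugs=drugs_by_key.get(key, []),
                events=events_by_key.get(key, []),
            )
        )
    return reports


def deduplicate(reports: list[AEReport]) -> list[AEReport]:
    """One report per case id: highest version, then latest receipt date,
    then a stable field-tuple tie-break.  Idempotent; preserves first-
    appearance order of cases."""
    best: dict[str, AEReport] = {}
    order: list[str] = []
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            order.append(r.case_id)
            continue
        key_new = (r.version, r.receipt_date, _tie_key(r))
        key_cur = (cur.version, cur.receipt_date, _tie_key(cur))
        if key_new > key_cur:
            best[r.case_id] = r
    return [best[cid] for cid in order]


def _tie_key(r: AEReport) -> tuple:
    return (
        r.gender,
        -1.0 if r.age_years is None else r.age_years,
        r.country or "",
        tuple(sorted(r.outcome_codes)),
        tuple((d.drug_name, d.role_code) for d in r.drugs),
        tuple((e.pt_code, e.pt_name) for e in r.events),
    )


def in_window(reports: list[AEReport], criteria: FilterCriteria) -> list[AEReport]:
    """Reports whose receipt date lies in the study window (inclusive).
    This set — all drugs, window-restricted — is the comparator database
    for the 2x2 tables."""
    return [
        r for r in reports if criteria.window_start <= r.receipt_date <= criteria.window_end
    ]


def apply_criteria(reports: list[AEReport], criteria: FilterCriteria) -> list[AEReport]:
    """The analysis set: in-window reports carrying the target drug with
    an allowed (suspect) role under any synonym."""
    return [
        r
        for r in in_window(reports, criteria)
        if r.has_drug(criteria.drug_synonyms, criteria.allowed_roles)
    ]


def resolve_outcome(r: AEReport) -> str:
    """The single outcome a report contributes, by severity precedence."""
    for code in OUTCOME_PRECEDENCE:
        if code in r.outcome_codes:
            return code
    return "OT"


def age_band(age: float | None) -> str:
    if age is None:
        return "Unknown"
    for label, (lo, hi) in zip(AGE_BANDS, _BAND_EDGES):
        if (lo is None or age >= lo) and (hi is None or age < hi):
            return label
    return "Unknown"


def summarize_demographics(reports: list[AEReport]) -> DemographicSummary:
    """Clinical-characteristics summary of the analysis set.

    Within each category the counts (including "Unknown") sum to the
    report total; percentages are half-up rounded to 2 decimals.
    """
    if not reports:
        raise ValueError("cannot summarize an empty analysis set")
    total = len(reports)
    gender: dict[str, int] = {}
    age: dict[str, int] = {b: 0 for b in AGE_BANDS}
    outcome: dict[str, int] = {}
    country: dict[str, int] = {}
    for r in reports:
        g = r.gender.capitalize() if r.gender != "unknown" else "Unknown"
        gender[g] = gender.get(g, 0) + 1
        age[age_band(r.age_years)] += 1
        lab = OUTCOME_LABELS[resolve_outcome(r)]
        outcome[lab] = outcome.get(lab, 0) + 1
        c = r.country if r.country is not None else "Unknown"
        country[c] = country.get(c, 0) + 1
    years = count_by_year(reports)

    def with_pct(counts: dict) -> dict:
        return {k: (v, percent(v, total)) for k, v in counts.items()}

    return DemographicSummary(
        total=total,
        gender=with_pct(gender),
        age_band=with_pct({b: age[b] for b in AGE_BANDS}),
        outcome=with_pct(outcome),
        country=with_pct(country),
        year=with_pct(years),
    )


def count_by_year(reports: list[AEReport]) -> dict[int, int]:
    """Report counts keyed by receipt year; years with no reports inside
    the observed span are reported as 0."""
    if not reports:
        return {}
    years = [r.receipt_date.year for r in reports]
    counts = {y: 0 for y in range(min(years), max(years) + 1)}
    for y in years:
        counts[y] += 1
    return counts


@dataclass(frozen=True)
class FlowLog:
    """Record-flow bookkeeping through the filtering cascade.

    Every raw record is retained, removed as a stale duplicate version,
    or excluded by exactly one criterion (window first, then drug/role);
    the four tallies sum to the raw count.
    """

    raw_records: int
    stale_versions: int
    excluded_window: int
    excluded_drug_role: int
    retained: int

    def __post_init__(self) -> None:
        total = self.stale_versions + self.excluded_window + self.excluded_drug_role + self.retained
        if total != self.raw_records:
            raise ValueError("flow tallies must sum to the raw record count")

    def lines(self) -> list[str]:
        return [
            f"raw records: {self.raw_records}",
            f"removed as stale duplicate versions: {self.stale_versions}",
            f"excluded (receipt date outside window): {self.excluded_window}",
            f"excluded (target drug not suspect): {self.excluded_drug_role}",
            f"retained in analysis set: {self.retained}",
        ]


def filter_with_flow(
    raw_reports: list[AEReport], criteria: FilterCriteria
) -> tuple[list[AEReport], list[AEReport], FlowLog]:
    """Full cascade: dedup -> window -> drug/role, with conservation
    bookkeeping.  Returns (analysis_set, in_window_database, flow)."""
    deduped = deduplicate(raw_reports)
    windowed = in_window(deduped, criteria)
    analysis = [
        r for r in windowed if r.has_drug(criteria.drug_synonyms, criteria.allowed_roles)
    ]
    flow = FlowLog(
        raw_records=len(raw_reports),
        stale_versions=len(raw_reports) - len(deduped),
        excluded_window=len(deduped) - len(windowed),
        excluded_drug_role=len(windowed) - len(analysis),
        retained=len(analysis),
    )
    return analysis, windowed, flow
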