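"""2x2 contingency tables per (target drug, PT) and SOC-level event counts.

The counting unit is the unique deduplicated report.  The comparator is
the full in-window database: for a PT, cell ``a`` counts reports that
carry the target drug as a suspect (PS/SS) and mention the PT at least
once; ``b`` the remaining target reports; ``c`` non-target reports with
the PT; ``d`` the rest.  A report listing the same PT twice counts once.
"""

from __future__ import annotations

from .model import AEReport, ContingencyTable, Vocabulary
from .ingest import percent

_SUSPECT_ROLES = ("PS", "SS")


def _is_target(report: AEReport, target_synonyms) -> bool:
    return report.has_drug(target_synonyms, _SUSPECT_ROLES)


def build_table(
    all_reports: list[AEReport], target_synonyms, pt_code: str
) -> ContingencyTable:
    """2x2 table for one PT against the full deduplicated in-window
    database (``all_reports`` must be the whole database, not only the
    target-drug analysis set)."""
    if not all_reports:
        raise ValueError("empty report database")
    a = b = c = d = 0
    for r in all_reports:
        target = _is_target(r, target_synonyms)
        event = pt_code in r.pt_codes()
        if target and event:
            a += 1
        elif target:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a=a, b=b, c=c, d=d)


def all_tables(
    all_reports: list[AEReport], target_synonyms
) -> dict[str, ContingencyTable]:
    """One table per PT observed in at least one target-drug report.

    All tables share the same N (the database size) and the same target
    margin a + b (the target-report count).
    """
    syn = frozenset(target_synonyms)
    target_flags = [_is_target(r, syn) for r in all_reports]
    n_target = sum(target_flags)
    n_total = len(all_reports)

    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for r, is_t in zip(all_reports, target_flags):
        for pt in r.pt_codes():
            if is_t:
                a_counts[pt] = a_counts.get(pt, 0) + 1
            else:
                c_counts[pt] = c_counts.get(pt, 0) + 1
    tables = {}
    for pt, a in a_counts.items():
        c = c_counts.get(pt, 0)
        tables[pt] = ContingencyTable(
            a=a, b=n_target - a, c=c, d=n_total - n_target - c
        )
    return tables


def soc_event_counts(
    target_reports: list[AEReport], vocabulary: Vocabulary
) -> dict[str, tuple[int, float]]:
    """Event occurrences per SOC over the target-drug analysis set.

    The unit is the distinct (report, PT) pair — one report mentioning
    three PTs contributes three occurrences — and percentages are over
    total occurrences, not reports.
    """
    counts: dict[str, int] = {}
    total = 0
    for r in target_reports:
        for pt in sorted(r.pt_codes()):
            soc = vocabulary.soc_of(pt)
            counts[soc] = counts.get(soc, 0) + 1
            total += 1
    return {soc: (n, percent(n, total)) for soc, n in counts.items()}
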