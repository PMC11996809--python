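import datetime as dt

import pytest

from pvsignal import (
    FilterCriteria,
    SyntheticConfig,
    apply_criteria,
    count_by_year,
    deduplicate,
    filter_with_flow,
    generate_reports,
    in_window,
    read_report_tables,
    summarize_demographics,
    write_report_tables,
)
from pvsignal.ingest import IngestError, age_band, percent, resolve_outcome
from conftest import TARGET_SYNONYMS, make_report


def test_read_tables_small_fixture(tmp_path, vocab):
    reports = [make_report(case_id=f"C{i}") for i in range(3)]
    write_report_tables(reports, tmp_path)
    assert len(read_report_tables(tmp_path, vocab)) == 3


def test_unknown_pt_code_fails_loudly(tmp_path, vocab):
    r = make_report(events=(("99999999", "Mystery event"),))
    write_report_tables([r], tmp_path)
    with pytest.raises(IngestError, match="99999999"):
        read_report_tables(tmp_path, vocab)


def test_orphan_rows_rejected(tmp_path, vocab):
    write_report_tables([make_report()], tmp_path)
    with open(tmp_path / "DRUG.tsv", "a") as fh:
        fh.write("GHOST\t1\tomadacycline\tPS\n")
    with pytest.raises(IngestError, match="GHOST"):
        read_report_tables(tmp_path, vocab)


def test_dedup_keeps_highest_version():
    v1 = make_report(version=1, receipt_date=dt.date(2020, 1, 1))
    v2 = make_report(version=2, receipt_date=dt.date(2020, 3, 1))
    assert deduplicate([v1, v2]) == [v2]
    assert deduplicate([v2, v1]) == [v2]


def test_dedup_tie_on_version_broken_by_date():
    early = make_report(version=1, receipt_date=dt.date(2020, 1, 1))
    late = make_report(version=1, receipt_date=dt.date(2021, 1, 1))
    assert deduplicate([early, late]) == [late]


def test_dedup_identity_and_idempotence():
    reports = [make_report(case_id=f"C{i}") for i in range(5)]
    assert deduplicate(reports) == reports
    once = deduplicate(reports + [make_report(case_id="C0", version=2)])
    assert deduplicate(once) == once


def test_dedup_cardinality_matches_distinct_cases():
    cfg = SyntheticConfig(n_reports=1000, duplicate_rate=0.1, seed=13)
    reports = generate_reports(cfg)
    assert len(deduplicate(reports)) == len({r.case_id for r in reports})


def test_criteria_validation():
    with pytest.raises(ValueError):
        FilterCriteria(drug_synonyms=frozenset())
    with pytest.raises(ValueError):
        FilterCriteria(drug_synonyms=frozenset({"x"}), allowed_roles=frozenset({"C"}))


def test_apply_criteria_hand_fixture(criteria):
    """Six reports: 2 PS in-window, 1 SS in-window, 1 C-only in-window,
    1 PS out-of-window, 1 other drug -> 3 retained."""
    fixture = [
        make_report(case_id="A", drugs=(("omadacycline", "PS"),)),
        make_report(case_id="B", drugs=(("NUZYRA", "PS"), ("drug_01", "C"))),
        make_report(case_id="C", drugs=(("nuzyra", "SS"),)),
        make_report(case_id="D", drugs=(("omadacycline", "C"),)),
        make_report(
            case_id="E",
            drugs=(("omadacycline", "PS"),),
            receipt_date=dt.date(2003, 12, 31),
        ),
        make_report(case_id="F", drugs=(("drug_02", "PS"),)),
    ]
    kept = apply_criteria(fixture, criteria)
    assert [r.case_id for r in kept] == ["A", "B", "C"]


def test_window_boundaries_inclusive(criteria):
    on_start = make_report(receipt_date=criteria.window_start)
    on_end = make_report(receipt_date=criteria.window_end)
    after = make_report(receipt_date=criteria.window_end + dt.timedelta(days=1))
    assert len(in_window([on_start, on_end, after], criteria)) == 2


def test_age_bands_half_open():
    assert age_band(17.9) == "<18"
    assert age_band(18.0) == "18-44"
    assert age_band(44.5) == "18-44"
    assert age_band(45.0) == "45-64"
    assert age_band(64.99) == "45-64"
    assert age_band(65.0) == "65-74"
    assert age_band(75.0) == ">=75"
    assert age_band(None) == "Unknown"


def test_outcome_precedence_severity_first():
    r = make_report(outcomes=("HO", "DE", "OT"))
    assert resolve_outcome(r) == "DE"
    assert resolve_outcome(make_report(outcomes=("HO", "DS"))) == "DS"


def test_percent_half_up_rounding():
    assert percent(218, 452) == 48.23
    assert percent(98, 452) == 21.68
    assert percent(1, 800) == 0.13  # 0.125 rounds half-up


def test_demographics_all_missing_age():
    reports = [make_report(case_id=f"C{i}", age_years=None) for i in range(4)]
    summary = summarize_demographics(reports)
    assert summary.age_band["Unknown"] == (4, 100.0)


def test_demographics_counts_conserved(planted_reports):
    analysis = deduplicate(planted_reports)[:1000]
    summary = summarize_demographics(analysis)
    for category in (summary.gender, summary.age_band, summary.outcome, summary.country):
        assert sum(c for c, _ in category.values()) == summary.total
        assert sum(p for _, p in category.values()) == pytest.approx(100.0, abs=0.06)


def test_count_by_year_gap_filling():
    assert count_by_year([]) == {}
    reports = [
        make_report(case_id=f"A{i}", receipt_date=dt.date(2019, 5, 1)) for i in range(2)
    ] + [make_report(case_id=f"B{i}", receipt_date=dt.date(2023, 5, 1)) for i in range(5)]
    assert count_by_year(reports) == {2019: 2, 2020: 0, 2021: 0, 2022: 0, 2023: 5}


def test_yearly_counts_sum_to_total(planted_reports):
    deduped = deduplicate(planted_reports)
    assert sum(count_by_year(deduped).values()) == len(deduped)


def test_flow_conservation(planted_reports, criteria):
    analysis, windowed, flow = filter_with_flow(planted_reports, criteria)
    assert flow.raw_records == len(planted_reports)
    assert (
        flow.stale_versions + flow.excluded_window + flow.excluded_drug_role + flow.retained
        == flow.raw_records
    )
    assert flow.retained == len(analysis)
    assert len(windowed) == flow.raw_records - flow.stale_versions - flow.excluded_window


def test_filter_dedup_commute(planted_reports, criteria):
    """Criteria depend only on fields constant across duplicate versions
    (all generated versions are in-window), so the two orders agree."""
    a = apply_criteria(deduplicate(planted_reports), criteria)
    b = deduplicate(apply_criteria(planted_reports, criteria))
    assert a == b
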