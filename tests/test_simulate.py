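import numpy as np
import pytest

from pvsignal import (
    SyntheticConfig,
    generate_reports,
    read_report_tables,
    write_report_tables,
)
from pvsignal.simulate import ConfigError
from conftest import TARGET_SYNONYMS


def test_empty_config_yields_empty_list():
    assert generate_reports(SyntheticConfig(n_reports=0, duplicate_rate=0.0)) == []


def test_same_seed_reproduces_identical_reports():
    cfg = lambda: SyntheticConfig(n_reports=300, seed=7)
    assert generate_reports(cfg()) == generate_reports(cfg())


def test_different_seeds_differ():
    a = generate_reports(SyntheticConfig(n_reports=300, seed=1))
    b = generate_reports(SyntheticConfig(n_reports=300, seed=2))
    assert a != b


def test_infeasible_planted_pair_rejected():
    with pytest.raises(ConfigError, match="infeasible"):
        SyntheticConfig(
            n_reports=10,
            background_event_prob=[0.5] * 69,
            planted=[("omadacycline", "10000001", 10.0)],
        )


def test_every_report_has_drug_and_event():
    reports = generate_reports(SyntheticConfig(n_reports=500, seed=3))
    assert all(r.drugs and r.events for r in reports)


def test_planted_relative_risk_recovered(planted_config, planted_reports):
    """Monte-Carlo check: with RR=10 planted at background 0.01 and 5%
    exposure over 20000 reports, the empirical rate ratio
    P(event|exposed)/P(event|unexposed) lands in [7, 13]."""
    pt = planted_config.planted[0][1]
    exp_n = exp_e = un_n = un_e = 0
    seen = set()
    for r in planted_reports:
        if r.case_id in seen:
            continue
        seen.add(r.case_id)
        exposed = any(
            d.drug_name.strip().casefold() in TARGET_SYNONYMS for d in r.drugs
        )
        has = pt in r.pt_codes()
        if exposed:
            exp_n += 1
            exp_e += has
        else:
            un_n += 1
            un_e += has
    ratio = (exp_e / exp_n) / (un_e / un_n)
    assert 7 <= ratio <= 13


def test_duplicate_versions_differ_only_in_version_and_date():
    reports = generate_reports(SyntheticConfig(n_reports=400, duplicate_rate=0.5, seed=9))
    by_case = {}
    for r in reports:
        by_case.setdefault(r.case_id, []).append(r)
    multi = [v for v in by_case.values() if len(v) > 1]
    assert multi, "expected some duplicated cases at rate 0.5"
    for versions in multi:
        v1, v2 = sorted(versions, key=lambda r: r.version)
        assert (v1.version, v2.version) == (1, 2)
        assert v1.receipt_date <= v2.receipt_date
        assert (v1.gender, v1.age_years, v1.country, v1.outcome_codes, v1.drugs, v1.events) == (
            v2.gender, v2.age_years, v2.country, v2.outcome_codes, v2.drugs, v2.events
        )


def test_table_row_counts(tmp_path):
    from conftest import make_report

    r = make_report(
        drugs=(("omadacycline", "PS"), ("drug_01", "C")),
        events=(("10000001", "Nausea"), ("10000002", "Vomiting"), ("10000013", "Tachycardia")),
    )
    paths = write_report_tables([r], tmp_path)
    assert sum(1 for _ in open(paths["drug"])) == 1 + 2
    assert sum(1 for _ in open(paths["reac"])) == 1 + 3
    assert sum(1 for _ in open(paths["demo"])) == 1 + 1


def test_write_read_round_trip(tmp_path):
    cfg = SyntheticConfig(n_reports=250, duplicate_rate=0.2, seed=11)
    reports = generate_reports(cfg)
    write_report_tables(reports, tmp_path)
    back = read_report_tables(tmp_path, cfg.vocabulary())
    assert len(back) == len(reports)
    key = lambda r: (r.case_id, r.version)
    for orig, readback in zip(sorted(reports, key=key), sorted(back, key=key)):
        assert readback.case_id == orig.case_id
        assert readback.receipt_date == orig.receipt_date
        assert readback.gender == orig.gender
        assert readback.country == orig.country
        assert readback.outcome_codes == orig.outcome_codes
        assert readback.drugs == orig.drugs
        assert readback.events == orig.events
        if orig.age_years is None:
            assert readback.age_years is None
        else:
            assert readback.age_years == pytest.approx(orig.age_years, abs=0.005)


def test_large_fixture_parses_cleanly(tmp_path, planted_config, planted_reports):
    """The 20000-report fixture writes and reads back with zero rejected
    rows and the raw record count matches the generator's output."""
    write_report_tables(planted_reports, tmp_path)
    back = read_report_tables(tmp_path, planted_config.vocabulary())
    assert len(back) == len(planted_reports)
    n_dupes = len(planted_reports) - len({r.case_id for r in planted_reports})
    assert len(back) == 20000 + n_dupes


def test_probability_tables_validated():
    with pytest.raises(ConfigError, match="gender_table"):
        SyntheticConfig(n_reports=5, gender_table={"male": 0.5, "female": 0.4})
    with pytest.raises(ConfigError, match="background_event_prob"):
        SyntheticConfig(n_reports=5, background_event_prob=[1.5] * 69)


def test_null_config_independence(planted_config):
    """Without planted pairs, target exposure and a given event are
    uncorrelated: a/(a+b) ~= c/(c+d) within binomial error at n=20000."""
    from pvsignal import all_tables

    cfg = SyntheticConfig(
        n_reports=20000,
        background_event_prob=[0.01] * 69,
        planted=[],
        duplicate_rate=0.0,
        seed=5,
    )
    reports = generate_reports(cfg)
    tables = all_tables(reports, TARGET_SYNONYMS)
    t = tables["10000001"]
    p_t = t.a / (t.a + t.b)
    p_bg = t.c / (t.c + t.d)
    # ~3.5 SD binomial band around the background rate at these sizes
    se = np.sqrt(p_bg * (1 - p_bg) / (t.a + t.b))
    assert abs(p_t - p_bg) < 3.5 * se
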