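import datetime as dt

import pytest

from pvsignal import (
    AEReport,
    DrugEntry,
    EventEntry,
    FilterCriteria,
    SyntheticConfig,
    default_vocabulary,
    generate_reports,
)

TARGET_SYNONYMS = frozenset({"omadacycline", "nuzyra"})


def make_report(
    case_id="C1",
    version=1,
    receipt_date=dt.date(2020, 6, 1),
    gender="female",
    age_years=50.0,
    country="United States",
    outcomes=("OT",),
    drugs=(("omadacycline", "PS"),),
    events=(("10000001", "Nausea"),),
):
    """Small hand-built report for unit fixtures."""
    return AEReport(
        case_id=case_id,
        version=version,
        receipt_date=receipt_date,
        gender=gender,
        age_years=age_years,
        country=country,
        outcome_codes=frozenset(outcomes),
        drugs=[DrugEntry(n, r) for n, r in drugs],
        events=[EventEntry(c, n) for c, n in events],
    )


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture
def criteria():
    return FilterCriteria(drug_synonyms=TARGET_SYNONYMS)


@pytest.fixture(scope="session")
def planted_config():
    """Reference recovery scenario: one planted pair at RR=10, background
    0.01, 5% target exposure, 20000 reports."""
    return SyntheticConfig(
        n_reports=20000,
        background_event_prob=[0.01] * 69,
        planted=[("omadacycline", "10000001", 10.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_reports(planted_config):
    return generate_reports(planted_config)
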