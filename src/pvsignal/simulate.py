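"""Synthetic FAERS-shaped report generator with planted drug-event signals.

The generator emulates the statistical structure a 2x2 disproportionality
analysis assumes: every report independently records drug exposures and
adverse events; under the null, drug and event indicators are independent;
for a *planted* pair (drug D, event E, relative risk RR) the conditional
event probability given exposure to D is RR times the background
probability (capped at 1).  Demographics (gender, age band, country,
outcome) are drawn from configurable category tables, receipt dates
uniformly from the study window, and a configurable fraction of cases is
emitted twice as two versions differing only in version number and
receipt date — exercising deduplication downstream.

Sampling uses one seeded NumPy generator in a fixed order (demographics,
drugs, events, outcome), so a config plus seed reproduces the report set
exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AEReport, DrugEntry, EventEntry, Vocabulary, default_vocabulary

# Category tables sized to the clinical-characteristics profile of a
# 452-report tetracycline-antibiotic case series (counts / 452).
_GENDER_TABLE = {"male": 172 / 452, "female": 218 / 452, "unknown": 62 / 452}
_AGE_TABLE = {
    "<18": 6 / 452,
    "18-44": 39 / 452,
    "45-64": 98 / 452,
    "65-74": 51 / 452,
    ">=75": 47 / 452,
    "unknown": 211 / 452,
}
_COUNTRY_TABLE = {
    "United States": 398 / 452,
    "China": 51 / 452,
    "Kuwait": 1 / 452,
    "Republic of Serbia": 1 / 452,
    "unknown": 1 / 452,
}
_OUTCOME_TABLE = {
    "OT": 341 / 452,
    "HO": 68 / 452,
    "DE": 36 / 452,
    "DS": 4 / 452,
    "LT": 3 / 452,
}
_ROLE_TABLE = {"PS": 0.55, "SS": 0.20, "C": 0.18, "I": 0.07}

# Uniform age draws within each band; the open-ended band is truncated at
# a realistic maximum.
_AGE_BOUNDS = {
    "<18": (0.0, 18.0),
    "18-44": (18.0, 45.0),
    "45-64": (45.0, 65.0),
    "65-74": (65.0, 75.0),
    ">=75": (75.0, 95.0),
}


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic reporting database.

    Defaults describe the reference simulation used throughout the test
    suite: 20000 reports, one target drug at 5% exposure among 19
    background drugs, the 69 bundled PTs with background reporting
    probabilities between 0.002 and 0.03, and a 10% duplicate-version
    rate over a 2004-01-01 .. 2024-03-31 receipt window.
    """

    n_reports: int = 20000
    n_drugs: int = 20  # including the target drug
    n_events: int = 69
    target_drug: str = "omadacycline"
    background_event_prob: np.ndarray | None = None  # length n_events
    drug_exposure_prob: np.ndarray | None = None  # length n_drugs; [0] = target
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    gender_table: dict[str, float] = field(default_factory=lambda: dict(_GENDER_TABLE))
    age_table: dict[str, float] = field(default_factory=lambda: dict(_AGE_TABLE))
    country_table: dict[str, float] = field(default_factory=lambda: dict(_COUNTRY_TABLE))
    outcome_table: dict[str, float] = field(default_factory=lambda: dict(_OUTCOME_TABLE))
    role_code_probs: dict[str, float] = field(default_factory=lambda: dict(_ROLE_TABLE))
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2004, 1, 1), _dt.date(2024, 3, 31))
    duplicate_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_event_prob is None:
            # log-spaced from common (3%) to rare (0.2%), fixed per config size
            self.background_event_prob = np.geomspace(0.03, 0.002, self.n_events)
        else:
            self.background_event_prob = np.asarray(self.background_event_prob, dtype=float)
        if self.drug_exposure_prob is None:
            probs = np.empty(self.n_drugs)
            probs[0] = 0.05  # target drug exposure
            probs[1:] = np.geomspace(0.15, 0.01, self.n_drugs - 1)
            self.drug_exposure_prob = probs
        else:
            self.drug_exposure_prob = np.asarray(self.drug_exposure_prob, dtype=float)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if len(self.background_event_prob) != self.n_events:
            raise ConfigError("background_event_prob length must equal n_events")
        if len(self.drug_exposure_prob) != self.n_drugs:
            raise ConfigError("drug_exposure_prob length must equal n_drugs")
        for vec, name in (
            (self.background_event_prob, "background_event_prob"),
            (self.drug_exposure_prob, "drug_exposure_prob"),
        ):
            if np.any((vec < 0) | (vec > 1)):
                raise ConfigError(f"{name} entries must lie in [0, 1]")
        for table, name in (
            (self.gender_table, "gender_table"),
            (self.age_table, "age_table"),
            (self.country_table, "country_table"),
            (self.outcome_table, "outcome_table"),
            (self.role_code_probs, "role_code_probs"),
        ):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in table.values()):
                raise ConfigError(f"{name} entries must be non-negative")
        if not (0 <= self.duplicate_rate <= 1):
            raise ConfigError("duplicate_rate must lie in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigError("date_range start must not exceed end")
        codes = self.pt_codes()
        code_index = {c: i for i, c in enumerate(codes)}
        for drug, pt, rr in self.planted:
            if rr <= 0:
                raise ConfigError(f"planted relative risk must be > 0 (got {rr})")
            if pt not in code_index:
                raise ConfigError(f"planted PT {pt!r} not among the config's events")
            if rr * self.background_event_prob[code_index[pt]] > 1.0:
                raise ConfigError(
                    f"infeasible planted pair ({drug}, {pt}): RR*p = "
                    f"{rr * self.background_event_prob[code_index[pt]]:.3f} > 1"
                )

    # -- derived vocabulary ---------------------------------------------
    def pt_codes(self) -> list[str]:
        base = sorted(default_vocabulary().pt_to_soc)
        if self.n_events <= len(base):
            return base[: self.n_events]
        extra = [f"SYN{k:06d}" for k in range(self.n_events - len(base))]
        return base + extra

    def drug_names(self) -> list[str]:
        return [self.target_drug] + [f"drug_{j:02d}" for j in range(1, self.n_drugs)]

    def vocabulary(self) -> Vocabulary:
        """Vocabulary covering exactly this config's PTs (trimmed or
        extended from the bundled one) plus the target-drug synonyms."""
        base = default_vocabulary()
        codes = self.pt_codes()
        socs = sorted(base.soc_names)
        pt_to_soc, pt_names = {}, {}
        for i, code in enumerate(codes):
            if code in base.pt_to_soc:
                pt_to_soc[code] = base.pt_to_soc[code]
                pt_names[code] = base.pt_name(code)
            else:
                pt_to_soc[code] = socs[i % len(socs)]
                pt_names[code] = f"Synthetic event {code}"
        synonyms = dict(base.synonyms)
        synonyms.setdefault(self.target_drug, frozenset({self.target_drug}))
        return Vocabulary(pt_to_soc=pt_to_soc, pt_names=pt_names, synonyms=synonyms)


def _sample_categories(rng: np.random.Generator, table: dict[str, float], n: int) -> np.ndarray:
    labels = list(table)
    probs = np.array([table[k] for k in labels], dtype=float)
    probs = probs / probs.sum()  # guard float drift
    return rng.choice(len(labels), size=n, p=probs)


def generate_reports(config: SyntheticConfig) -> list[AEReport]:
    """Draw a raw (possibly duplicated) report list from the config.

    Deterministic given ``config.seed``.  Every report carries at least
    one drug and one event (zero draws are redrawn); a ``duplicate_rate``
    fraction of cases is emitted as two versions that differ only in
    version number and receipt date.
    """
    config.validate()
    n = config.n_reports
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)
    vocab = config.vocabulary()
    pt_codes = config.pt_codes()
    drug_names = config.drug_names()
    target_variants = sorted(vocab.synonyms_of(config.target_drug))

    # 1. demographics (gender, age, country, receipt date)
    gender_labels = list(config.gender_table)
    gender_idx = _sample_categories(rng, config.gender_table, n)
    age_labels = list(config.age_table)
    age_idx = _sample_categories(rng, config.age_table, n)
    age_u = rng.random(n)
    country_labels = list(config.country_table)
    country_idx = _sample_categories(rng, config.country_table, n)
    start, end = config.date_range
    n_days = (end - start).days + 1
    day_offsets = rng.integers(0, n_days, size=n)

    # 2. drug exposure matrix (n x n_drugs) with >= 1 drug per report
    exposed = rng.random((n, config.n_drugs)) < config.drug_exposure_prob
    empty = ~exposed.any(axis=1)
    while empty.any():
        exposed[empty] = rng.random((empty.sum(), config.n_drugs)) < config.drug_exposure_prob
        empty = ~exposed.any(axis=1)
    role_labels = list(config.role_code_probs)
    role_idx = _sample_categories(
        rng, config.role_code_probs, n * config.n_drugs
    ).reshape(n, config.n_drugs)
    variant_idx = rng.integers(0, len(target_variants), size=n)

    # 3. events: background probabilities, lifted for planted pairs on
    #    reports exposed to the planted drug; >= 1 event per report
    drug_index = {name: j for j, name in enumerate(drug_names)}
    pt_index = {code: i for i, code in enumerate(pt_codes)}
    prob = np.tile(config.background_event_prob, (n, 1))
    for drug, pt, rr in config.planted:
        j = drug_index[drug]
        i = pt_index[pt]
        prob[exposed[:, j], i] = min(rr * config.background_event_prob[i], 1.0)
    has_event = rng.random((n, config.n_events)) < prob
    empty = ~has_event.any(axis=1)
    while empty.any():
        has_event[empty] = rng.random((empty.sum(), config.n_events)) < prob[empty]
        empty = ~has_event.any(axis=1)

    # 4. outcome: one code per report
    outcome_labels = list(config.outcome_table)
    outcome_idx = _sample_categories(rng, config.outcome_table, n)

    # 5. duplicate versions
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_lag = rng.integers(1, 181, size=n)  # earlier version, 1..180 days before

    reports: list[AEReport] = []
    for i in range(n):
        band = age_labels[age_idx[i]]
        if band in _AGE_BOUNDS:
            lo, hi = _AGE_BOUNDS[band]
            age: float | None = lo + age_u[i] * (hi - lo)
        else:
            age = None
        country_label = country_labels[country_idx[i]]
        country = None if country_label == "unknown" else country_label
        date = start + _dt.timedelta(days=int(day_offsets[i]))
        drugs = []
        for j in np.flatnonzero(exposed[i]):
            name = (
                target_variants[variant_idx[i]] if j == 0 else drug_names[j]
            )
            drugs.append(DrugEntry(drug_name=name, role_code=role_labels[role_idx[i, j]]))
        events = [
            EventEntry(pt_code=pt_codes[k], pt_name=vocab.pt_name(pt_codes[k]))
            for k in np.flatnonzero(has_event[i])
        ]
        common = dict(
            case_id=f"C{i:07d}",
            gender=gender_labels[gender_idx[i]],
            age_years=age,
            country=country,
            outcome_codes=frozenset({outcome_labels[outcome_idx[i]]}),
            drugs=drugs,
            events=events,
        )
        if dup_mask[i]:
            early = max(start, date - _dt.timedelta(days=int(dup_lag[i])))
            reports.append(AEReport(version=1, receipt_date=early, **common))
            reports.append(AEReport(version=2, receipt_date=date, **common))
        else:
            reports.append(AEReport(version=1, receipt_date=date, **common))
    return reports


# ---------------------------------------------------------------------------
# flat-table output (DEMO / DRUG / REAC / OUTC)

DEMO_COLUMNS = ["case_id", "version", "receipt_date", "gender", "age_years", "country"]
DRUG_COLUMNS = ["case_id", "version", "drug_name", "role_code"]
REAC_COLUMNS = ["case_id", "version", "pt_code", "pt_name"]
OUTC_COLUMNS = ["case_id", "version", "outcome_code"]

TABLE_FILES = {
    "demo": "DEMO.tsv",
    "drug": "DRUG.tsv",
    "reac": "REAC.tsv",
    "outc": "OUTC.tsv",
}


def write_report_tables(reports: list[AEReport], out_dir: str | Path) -> dict[str, Path]:
    """Write the four linked flat tables (DEMO, DRUG, REAC, OUTC) as TSV,
    keyed by (case_id, version).  Returns the paths written."""
    if not reports:
        raise ValueError("cannot write tables for an empty report list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, outc = [], [], [], []
    for r in reports:
        key = (r.case_id, r.version)
        demo.append(
            key
            + (
                r.receipt_date.isoformat(),
                r.gender,
                "" if r.age_years is None else f"{r.age_years:.2f}",
                "" if r.country is None else r.country,
            )
        )
        for d in r.drugs:
            drug.append(key + (d.drug_name, d.role_code))
        for e in r.events:
            reac.append(key + (e.pt_code, e.pt_name))
        for code in sorted(r.outcome_codes):
            outc.append(key + (code,))
    frames = {
        "demo": pd.DataFrame(demo, columns=DEMO_COLUMNS),
        "drug": pd.DataFrame(drug, columns=DRUG_COLUMNS),
        "reac": pd.DataFrame(reac, columns=REAC_COLUMNS),
        "outc": pd.DataFrame(outc, columns=OUTC_COLUMNS),
    }
    paths = {}
    for name, frame in frames.items():
        path = out_dir / TABLE_FILES[name]
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
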