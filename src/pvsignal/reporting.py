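"""End-to-end pipeline orchestration and publication-style table output.

``run_pipeline`` executes read -> dedup -> filter -> demographics ->
contingency -> statistics -> classification and writes:

* a clinical-characteristics table (counts + percentages),
* a signal table (positives only) rendered as ``ROR (95%CI)`` and
  ``IC (IC-2SD)`` at 2 decimals, sorted by SOC then descending case count,
* SOC-level event counts, yearly report counts,
* a full per-PT statistics table at full precision, and
* a record-flow log.

Rounding to 2 decimals (half-up) happens only here; all statistics are
carried at full precision upstream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from .contingency import all_tables, soc_event_counts
from .ingest import (
    DemographicSummary,
    FilterCriteria,
    FlowLog,
    filter_with_flow,
    read_report_tables,
    summarize_demographics,
    count_by_year,
)
from .model import ContingencyTable, SignalStats, Vocabulary, load_vocabulary
from .stats import BcpnnHyperparams, evaluate_table


def round2(x: float) -> str:
    """Half-up rounding to 2 decimals, as printed in report tables."""
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    data_dir: Path
    vocabulary_path: Path | None = None  # None -> bundled default
    criteria: FilterCriteria = field(
        default_factory=lambda: FilterCriteria(frozenset({"omadacycline", "nuzyra"}))
    )
    bcpnn: BcpnnHyperparams = field(default_factory=BcpnnHyperparams)
    output_dir: Path = Path("pvsignal_out")
    label_pts: frozenset[str] = frozenset()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        criteria = FilterCriteria(
            drug_synonyms=frozenset(raw["drug_synonyms"]),
            allowed_roles=frozenset(raw.get("allowed_roles", ["PS", "SS"])),
            window_start=_dt.date.fromisoformat(raw.get("window_start", "2004-01-01")),
            window_end=_dt.date.fromisoformat(raw.get("window_end", "2024-03-31")),
        )
        return cls(
            data_dir=Path(raw["data_dir"]),
            vocabulary_path=Path(raw["vocabulary"]) if "vocabulary" in raw else None,
            criteria=criteria,
            bcpnn=BcpnnHyperparams(**raw.get("bcpnn", {})),
            output_dir=Path(raw.get("output_dir", "pvsignal_out")),
            label_pts=frozenset(raw.get("label_pts", [])),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    """In-memory results of one run (files are written alongside)."""

    demographics: DemographicSummary
    tables: dict[str, ContingencyTable]
    stats: dict[str, SignalStats]
    soc_counts: dict[str, tuple[int, float]]
    year_counts: dict[int, int]
    flow: FlowLog
    signal_rows: pd.DataFrame


def format_signal_table(
    stats: dict[str, SignalStats],
    tables: dict[str, ContingencyTable],
    vocabulary: Vocabulary,
    label_pts=frozenset(),
) -> pd.DataFrame:
    """Publication-shaped signal table: positives only, one row per PT,
    ``N`` (= a), ``ROR (95%CI)`` and ``IC (IC-2SD)`` at 2 decimals, a
    ``*`` marking label-listed events, sorted by SOC then descending N
    with ties by PT name."""
    rows = []
    for pt, s in stats.items():
        if not s.signal:
            continue
        t = tables[pt]
        name = vocabulary.pt_name(pt)
        rows.append(
            {
                "soc": vocabulary.soc_of(pt),
                "pt_code": pt,
                "pt": name + ("*" if pt in label_pts else ""),
                "N": t.a,
                "ROR (95%CI)": f"{round2(s.ror)} ({round2(s.ci_low)},{round2(s.ci_high)})",
                "IC (IC-2SD)": f"{round2(s.ic)} ({round2(s.ic_2sd)})",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["soc", "pt_code", "pt", "N", "ROR (95%CI)", "IC (IC-2SD)"]
    )
    if len(frame):
        frame = frame.sort_values(
            ["soc", "N", "pt"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return frame


def _demographics_frame(summary: DemographicSummary) -> pd.DataFrame:
    rows = []
    for category, mapping in (
        ("Gender", summary.gender),
        ("Age (year)", summary.age_band),
        ("Outcome", summary.outcome),
        ("Reported countries", summary.country),
        ("Reported year", summary.year),
    ):
        for label, (count, pct) in mapping.items():
            rows.append(
                {
                    "category": category,
                    "label": str(label),
                    "count": count,
                    "percent": f"{round2(pct)}%",
                }
            )
    return pd.DataFrame(rows, columns=["category", "label", "count", "percent"])


def _stats_frame(
    stats: dict[str, SignalStats],
    tables: dict[str, ContingencyTable],
    vocabulary: Vocabulary,
) -> pd.DataFrame:
    rows = []
    for pt in sorted(stats):
        s, t = stats[pt], tables[pt]
        rows.append(
            {
                "pt_code": pt,
                "pt_name": vocabulary.pt_name(pt),
                "soc": vocabulary.soc_of(pt),
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "N": t.n,
                "ror": "" if s.ror is None else repr(s.ror),
                "ci_low": "" if s.ci_low is None else repr(s.ci_low),
                "ci_high": "" if s.ci_high is None else repr(s.ci_high),
                "ic": repr(s.ic),
                "ic_2sd": repr(s.ic_2sd),
                "ror_positive": s.ror_positive,
                "bcpnn_positive": s.bcpnn_positive,
                "signal": s.signal,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the artifact bundle to
    ``config.output_dir``.  Deterministic: the same inputs reproduce
    byte-identical TSVs."""
    vocabulary = (
        load_vocabulary(config.vocabulary_path)
        if config.vocabulary_path is not None
        else None
    )
    if vocabulary is None:
        from .model import default_vocabulary

        vocabulary = default_vocabulary()
    unknown_label = config.label_pts - set(vocabulary.pt_to_soc)
    if unknown_label:
        raise ValueError(f"label_pts not in vocabulary: {sorted(unknown_label)[:10]}")

    raw = read_report_tables(config.data_dir, vocabulary)
    analysis, database, flow = filter_with_flow(raw, config.criteria)

    tables = all_tables(database, config.criteria.drug_synonyms)
    stats = {
        pt: evaluate_table(t, config.bcpnn) for pt, t in sorted(tables.items())
    }
    demographics = summarize_demographics(analysis) if analysis else None
    socs = soc_event_counts(analysis, vocabulary) if analysis else {}
    years = count_by_year(analysis)
    signal_rows = format_signal_table(stats, tables, vocabulary, config.label_pts)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if demographics is not None:
        _demographics_frame(demographics).to_csv(
            out / "demographics.tsv", sep="\t", index=False
        )
    signal_rows.to_csv(out / "signal_table.tsv", sep="\t", index=False)
    _stats_frame(stats, tables, vocabulary).to_csv(
        out / "signal_stats.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(soc, n, f"{round2(p)}%") for soc, (n, p) in sorted(socs.items())],
        columns=["soc", "event_count", "percent"],
    ).to_csv(out / "soc_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(years.items()), columns=["year", "count"]
    ).to_csv(out / "year_counts.tsv", sep="\t", index=False)
    (out / "flow_log.txt").write_text("\n".join(flow.lines()) + "\n")

    return PipelineResult(
        demographics=demographics,
        tables=tables,
        stats=stats,
        soc_counts=socs,
        year_counts=years,
        flow=flow,
        signal_rows=signal_rows,
    )
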