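"""Generate a synthetic spontaneous-reporting database and write it as
the four linked flat tables (DEMO, DRUG, REAC, OUTC).

The database has 5000 reports, 20 drugs, the 69 bundled adverse-event
preferred terms, and one planted association: reports exposed to
omadacycline carry "Nausea" at 10x the background probability.
"""

from pathlib import Path

from pvsignal import SyntheticConfig, generate_reports, write_report_tables

config = SyntheticConfig(
    n_reports=5000,
    planted=[("omadacycline", "10000001", 10.0)],  # Nausea at RR = 10
    seed=1,
)
reports = generate_reports(config)
out = Path("scratch_example_db")
write_report_tables(reports, out)

n_cases = len({r.case_id for r in reports})
print(f"records written: {len(reports)} ({n_cases} cases, "
      f"{len(reports) - n_cases} duplicate versions)")
print(f"tables in: {out}/")
# The record count exceeds the case count because a fraction of cases is
# emitted twice, as two versions differing only in version number and
# receipt date — this is what deduplication removes downstream.
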