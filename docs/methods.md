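# Methods

## The analysis

The package implements single-drug disproportionality screening of a
spontaneous adverse-event reporting database.  The counting unit
everywhere is the unique, deduplicated report.  For a target drug and
each preferred term (PT) co-reported with it at least once, a 2×2 table
(a, b, c, d) is built against the **full in-window database** — the
comparator is "all other drugs", not a restricted class — and the
reporting odds ratio (ROR) and the BCPNN information component (IC) are
computed.  A pair is a suspicious signal only when both are positive.

Assumptions inherited from the 2×2 design: reports are independent;
events within a report enter the table only through presence/absence (a
PT listed twice counts once); no adjustment is made for age, sex,
masking or reporting trends, and no multiple-testing correction is
applied — the dual rule itself is the false-positive control.

## Statistics

**ROR.** ROR = (a·d)/(b·c); Wald 95% CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))
with z = 1.96 fixed.  The interval is multiplicatively symmetric:
√(ci_low·ci_high) = ROR, which is also the internal consistency check
used against published signal tables.  Any zero cell makes the estimate
*not estimable*; we deliberately apply no Haldane 0.5 correction rather
than silently invent an estimate, and a not-estimable ROR can never be
positive.  Positivity: a ≥ 3 co-reports and ci_low > 1 (strict).  The
a ≥ 3 gate is the standard case-count threshold in this literature.

**BCPNN.** The closed-form posterior moments of Bate et al. (1998) with
Dirichlet/Beta priors α₁ = β₁ = γ₁₁ = 1, α = β = 2 (the choice for which
E(IC) = 0 on an empty database under independence):

    γ     = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁))
    E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
    V(IC) = (1/ln2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                     + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                     + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ]

Positivity: IC−2SD = E(IC) − 2√V(IC) > 0.  The prior smoothing handles
zero cells, so no correction is needed.  As all cells grow at fixed
proportions, E(IC) → log₂(a·N/((a+b)(a+c))); the tests verify monotone
convergence to within 0.01 bits at 1000× scale, and agreement of both
closed forms with independent 50-digit mpmath re-implementations to
1e-9 relative error.

All statistics are carried at full precision; rounding (half-up, 2
decimals) happens only in the reporting layer.

## Data handling conventions

* **Deduplication.** One report per case id: highest version wins, ties
  broken by latest receipt date, then by a stable field-tuple ordering.
  This is our stated convention (databases such as FAERS are usually
  deduplicated upstream by the extraction tool); it is idempotent and
  order-commutes with filtering whenever duplicate versions share the
  window.
* **Inclusion.** Receipt date inside the study window (inclusive on both
  ends; default 2004-01-01..2024-03-31) and the target drug present
  under any synonym (exact match after case-folding and trimming — no
  fuzzy matching, for reproducibility) with role primary or secondary
  suspect.  Reports where the target appears only as concomitant or
  interacting are excluded.
* **Outcomes.** When a report carries several outcome codes it
  contributes one, by severity precedence Death > Life-threatening >
  Disability > Hospitalization > Other, so outcome counts sum to the
  report total.
* **Age bands.** <18, [18,45), [45,65), [65,75), [75,∞), Unknown.
* **SOC aggregation.** Counts distinct (report, PT) pairs grouped by
  system organ class; percentages are over total event occurrences, not
  reports, since one report contributes several PTs.
* **Vocabulary.** Only the PT and SOC levels of the MedDRA hierarchy are
  modelled; the bundled toy vocabulary (69 PTs, 17 SOCs, no version
  claim) exists so that the pipeline runs without a MedDRA licence.
  Codes, not names, are join keys.

## The synthetic generator

`SyntheticConfig`/`generate_reports` emulate the statistical structure
the 2×2 analysis assumes: each report independently draws demographics,
a drug-exposure vector, per-PT event indicators, and one outcome, from a
single seeded NumPy generator in that fixed order.  For a planted triple
(drug, PT, RR) the conditional event probability given exposure is
RR × background (validated RR·p ≤ 1).  Defaults describe the reference
simulation used throughout the tests: 20000 reports; 20 drugs with the
target at 5% exposure; the 69 bundled PTs with background reporting
probabilities log-spaced 0.03..0.002 (a flat 0.01 in the recovery
suite); demographics tables proportional to a published 452-case
tetracycline-antibiotic series; 10% of cases emitted as two versions
differing only in version number and receipt date.

Reports drawn with zero drugs or zero events are redrawn.  The redraw
conditions on "at least one event" and therefore inflates marginal event
probabilities slightly in both exposure arms; the inflation largely
cancels in the rate ratio, which is why the Monte-Carlo recovery band
for RR = 10 is [7, 13] rather than a tight interval.

What the generator does **not** model — and hence what passing tests do
not establish about real data: within-report event correlation,
reporting trends over time, masking/competition between drugs,
stratification-worthy confounding, free-text name noise beyond letter
case, and non-year age units.

## Problem sizes and numerical choices

The calibration and recovery suites use ten seeded 20000-report
databases each — large enough that the planted-pair ROR concentrates
well within a factor of 2 of the planted RR = 10 and that a ≥ 3 pairs
are plentiful under the null, while a full suite run stays around ten
seconds.  Null calibration measures the mean fraction of a ≥ 3 pairs
flagged (observed ≈ 1–2%, bound 5%).  Ties in the signal-table sort are
broken by SOC, then descending co-report count, then PT name — a
declared convention, since published tables rarely state theirs.

One published-consistency caveat: for the infusion-site-phlebitis row of
the published signal table the geometric mean of the printed CI bounds
is 1224.666, which rounds to 1224.67 against a printed ROR of 1224.66.
The discrepancy is exactly the propagated rounding of the printed
bounds (±0.005 on each bound moves the geometric mean by up to ±0.008),
so the consistency test asserts 2-dp equality only where the printed
precision can resolve it and otherwise agreement within the propagated
interval.

## Limitations

Desk-scale synthetic databases cannot reproduce a published FAERS case
series; the acceptance surface is therefore formula-convention
consistency, printed-count arithmetic, and planted-signal behaviour.
The BCPNN variant and its hyperparameters, the deduplication rule, the
a ≥ 3 gate and the receipt-date choice are documented conventions of
this package, standard in the field but not uniquely determined by any
single published description.
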