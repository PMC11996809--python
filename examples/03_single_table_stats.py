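"""Disproportionality statistics for a single 2x2 table.

The table below says: of N = 1000 reports, 20 mention both the target
drug and the event, 80 the drug only, 50 the event only, 850 neither.
"""

from pvsignal import ContingencyTable, evaluate_table

t = ContingencyTable(a=20, b=80, c=50, d=850)
s = evaluate_table(t)

print(f"2x2 table: a={t.a} b={t.b} c={t.c} d={t.d}  (N={t.n})")
print(f"ROR  = {s.ror:.4f}  95% CI ({s.ci_low:.4f}, {s.ci_high:.4f})")
print(f"IC   = {s.ic:.4f} bits   IC-2SD = {s.ic_2sd:.4f}")
print(f"ROR positive (a>=3 and CI low > 1): {s.ror_positive}")
print(f"BCPNN positive (IC-2SD > 0):        {s.bcpnn_positive}")
print(f"signal (both positive):             {s.signal}")
# ROR = (20*850)/(80*50) = 4.25: the event is reported ~4x more often
# with the drug than without.  Both lower bounds exceed their thresholds,
# so the pair is flagged as a suspicious signal.
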