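"""Delta-delta-Ct analysis of a qPCR pathway array.

Simulates an 84-gene panel plus 5 housekeeping genes (Gusb, Hprt1,
Hsp90ab1, Gapdh, Actb) with 11 planted expression shifts, normalizes each
sample against the housekeeping mean, and applies the fold-change-3 /
p<0.05 selection.
"""
from orthoconcord import SimConfig, ddct_analysis, simulate_qpcr

table, design, truth = simulate_qpcr(SimConfig(seed=2))
report = ddct_analysis(table, design, "KO24", "WT24", fc_cutoff=3.0, p_max=0.05)

selected = report[report.selected].sort_values("fc", ascending=False)
print(f"planted genes: {len(truth['planted'])}, selected: {len(selected)}")
for _, row in selected.iterrows():
    planted = 2.0 ** truth["planted"].get(row.gene, {"log2fc": 0.0})["log2fc"]
    print(f"  {row.gene}: FC {row.fc:6.2f} ({row.direction:<4}) "
          f"p={row.p_value:.2e}  planted FC {planted:6.2f}")
# Measured fold changes should track the planted ones; genes without a
# planted shift stay unselected at the FC 3 / p<0.05 cutoff.
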