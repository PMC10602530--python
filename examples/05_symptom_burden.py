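"""Ordinal symptom-burden analysis: fold screen, Fisher tests, heatmap.

The 63-variable ordinal (0-3) symptom table is screened for variables
enriched in severe ME/CFS relative to the MS disease controls (relative
mean ordinal intensity fold >= 1.5), tested by two-sided Fisher exact
tests on presence/absence with Benjamini-Hochberg adjustment, and
exported as a heatmap-ready matrix.
"""

import scrsdx as sx
from scrsdx.clinical import heatmap_matrix, symptom_selection

cohort = sx.generate_cohort(sx.default_config(seed=2), include_spectra=False)
table = cohort.symptom_table

sel = symptom_selection(table)  # severe ME vs MS reference
n_inc = int(sel["included"].sum())
n_sig = int(sel["significant"].sum())
print(f"{len(sel)} symptom variables; {n_inc} pass the >=1.5-fold screen, "
      f"{n_sig} significant after BH (adj p < 0.05)")

top = sel[sel["included"]].sort_values("fold", ascending=False).head(5)
cols = ["mean_SevME", "mean_MS", "fold", "p", "p_adj"]
print("\nTop variables by severe-ME/MS fold:")
print(top[cols].to_string(float_format=lambda v: f"{v:.3f}"))

matrix, groups = heatmap_matrix(sel, table)
print(f"\nHeatmap matrix: {matrix.shape[0]} variables x {matrix.shape[1]} subjects, "
      f"{int(matrix.isna().sum().sum())} missing entries (rendered gray),")
print("subjects ordered HC, mild ME, moderate ME, severe ME, MS;")
print("rows ordered by descending fold difference.")
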