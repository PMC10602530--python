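"""Generate a synthetic PBMC Raman cohort and inspect its clinical structure.

The default configuration emulates a 98-subject study (16 healthy
controls, 61 ME/CFS patients split 25/15/21 by severity, 21 MS disease
controls) with ~30 cells per subject.  Here we generate the subjects and
clinical scores only (no spectra) to look at the cohort table.
"""

import scrsdx as sx

cohort = sx.generate_cohort(sx.default_config(seed=1), include_spectra=False)
man = cohort.manifest()

print(man.groupby("group", sort=False).size().rename("subjects").to_string())
print()
summary = man.groupby("group")[["fss", "sf36_pf"]].median()
print("Median clinical scores per group:")
print(summary.to_string())
print()
me = man[man["group"].isin(["MildME", "ModME", "SevME"])]
print(f"Median FSS over all {len(me)} ME/CFS subjects: {me['fss'].median():.0f}")
print("(Fatigue Severity Scale 9-63: higher = more fatigued; the generator")
print(" pins each group's median exactly via stratified score assignment.)")
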