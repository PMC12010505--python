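"""Motif usage: tables, sex-normalized group tests, time course.

Usage is the fraction of session frames spent in each motif. Group
comparisons run on usage relative to sex-matched controls, with
Benjamini-Hochberg control of the false discovery rate across motifs;
time-binned occupancy feeds a repeated-measures analysis and a
habituation / sensitization call per motif.
"""

from motifkit.synthetic import default_spec, generate_cohort
from motifkit.usage import (habituation_labels, relative_usage,
                            time_binned_usage, usage_table, usage_tests)

data = generate_cohort(default_spec(n_subjects=4, session_minutes=10.0,
                                    seed=7))
m = data.spec.n_motifs

usage = usage_table(data.labels, m)
print("usage head (frames / seconds / percent):")
print(usage.head(4).to_string(index=False))

rel = relative_usage(usage, data.cohort, baseline="WT")
tests = usage_tests(rel, data.cohort, factor="genotype", alpha=0.05)
sig = tests[tests["significant"]]
print(f"\nmotifs with q <= 0.05: {sorted(sig['motif'].tolist())}")
print(tests.sort_values("q").head(6).to_string(index=False))

# occupancy over 2-minute bins and habituation classes from control slopes
binned = time_binned_usage(data.labels, m, bin_minutes=2.0)
hab = habituation_labels(binned, data.cohort, control="WT")
print("\nhabituation class counts:")
print(hab["class"].value_counts().to_string())
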