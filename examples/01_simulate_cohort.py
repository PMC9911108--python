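"""Simulate a cohort-shaped table and run the preprocessing stages.

The `cohort_shaped` preset mimics the motivating study's dimensions: 91
children, 87 clinical variables, ~37% steroid-resistant, and nine variables
with 60% missing cells that the >50% missingness filter removes.
"""

from hingeselect import drop_high_missing, standardize
from hingeselect.synthetic import generate, presets, write_cohort_csv

table, truth = generate(presets()["cohort_shaped"], seed=1)
pos, neg = table.class_counts()
print(f"simulated cohort: {table.n_subjects} subjects x {len(table.variables)} variables")
print(f"class balance: {pos} resistant (+1) vs {neg} sensitive (-1)")

filtered = drop_high_missing(table, 0.5)
print(f"after the >50% missingness filter: {len(filtered.variables)} variables remain")

std = standardize(filtered)
col = std.data[std.variables[0]]
print(f"first variable after scaling: mean={col.mean():+.2e}, sd={col.std(ddof=0):.3f}")
print(f"planted signals: {sorted(truth.signal_variables)}")

write_cohort_csv(table, "scratch_cohort.csv")
print("cohort written to scratch_cohort.csv (CSV dialect: NA = missing)")
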