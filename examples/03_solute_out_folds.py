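"""Solute-out fold assignment and partition auditing.

Shows how all records of a compound are held out together, so every
out-of-fold prediction is for a compound the fold model never saw.
"""

import numpy as np

from dooit2 import SynthConfig, assign_folds, audit_partition, generate_dataset

table, _ = generate_dataset(SynthConfig(n_solutes=20, seed=0))
assignment = assign_folds(table.group_sizes(), k=5, seed=0)

labels = table.group_labels()
report = audit_partition(assignment, labels)
print("partition audit passed:", report.passed)

totals = np.zeros(5, dtype=int)
for g, f in assignment.group_to_fold.items():
    totals[f] += table.group_sizes()[g]
print("records per fold:", totals.tolist(), "(balanced by greedy largest-first packing)")
print("solutes in fold 0:", sorted(g for g, f in assignment.group_to_fold.items() if f == 0))
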