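"""Homopolymer indel-error simulation on one transcript.

Plans 2 errors per 100 bases on a sequence, shows that edits target the
longest homopolymer runs, and prints the length bookkeeping.
"""

import numpy as np

from lncclass import TranscriptRecord, find_homopolymer_runs, simulate_record

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=500))
record = TranscriptRecord("demo", seq)

runs = find_homopolymer_runs(record)
print(f"{record.length} nt, {len(runs)} homopolymer runs, "
      f"longest {max(r.length for r in runs)} nt")

mutated, plan = simulate_record(record, p=0.02, seed=1)
print(f"rate 2/100 -> {plan.n_edits} single-base edits")
for edit in plan.edits[:5]:
    print(f"  {edit.op:<6} one {edit.run.base} in run at {edit.run.start} "
          f"(length {edit.run.length})")
n_ins = sum(e.op == "insert" for e in plan.edits)
print(f"length {record.length} -> {mutated.length} "
      f"({n_ins} insertions, {plan.n_edits - n_ins} deletions)")
# Edits always fall inside existing homopolymer runs (the error mode of
# 454/PacBio chemistry) and the longest runs are hit first.
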