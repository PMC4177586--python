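"""Calibrated k-mer usage features for a single transcript.

Builds the 1,364-pattern table (k = 1..5), featurizes one short sequence
and prints a few calibrated frequencies f_i = (c_i / s_k) * w_k.
"""

from lncclass import TranscriptRecord, default_calibration, enumerate_patterns, featurize

table = enumerate_patterns(1, 5)
cal = default_calibration(1, 5)
record = TranscriptRecord("demo", "ATGGCCGCTGCGGCAGCG" * 20)
fv = featurize(record, table, cal)

print(f"pattern table: {len(table)} features (k = {table.k_min}..{table.k_max})")
print(f"transcript {record.id}: {record.length} nt")
for pattern in ("G", "GC", "GCG", "GCGG", "GCGGC"):
    i = table.index_of(pattern)
    w = cal.weights[len(pattern)]
    print(f"  f({pattern:<6}) = {fv.values[i]:.6f}   (raw frequency {fv.values[i] / w:.4f}, weight {w:g})")
# Each f_i is the sliding-window frequency of that pattern times the
# length-dependent weight 4^(k-5); raw per-k frequencies sum to 1.
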